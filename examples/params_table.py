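"""Reproduce the published parameter table.

Builds all three segmentation families (FCN, SegNet, Sub-Pixel) in their
baseline and tiny (separable-convolution) forms at the resolved head
configurations, counts parameters with the closed-form layer rules, and
prints the totals together with the tiny-vs-baseline reduction
percentages.

Run:  python examples/params_table.py
"""

from tinyseg.archspec import PUBLISHED_CONFIGS, build_model, count_parameters


def main():
    print(f"{'model':<18}{'classes':>8}{'trainable':>14}{'total':>14}")
    totals = {}
    for (family, tiny), kwargs in PUBLISHED_CONFIGS.items():
        spec = build_model(family, tiny, **kwargs)
        report = count_parameters(spec)
        name = ("tiny-" if tiny else "") + family
        totals[name] = report.total
        print(f"{name:<18}{spec.n_classes:>8}{report.trainable:>14,}{report.total:>14,}")

    print("\nreduction from separable convolutions:")
    for family in ("fcn", "segnet", "subpixel"):
        pct = 100.0 * (1.0 - totals[f"tiny-{family}"] / totals[family])
        print(f"  {family:<10} {pct:6.2f} %")


if __name__ == "__main__":
    main()
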