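"""Cross-country benchmarks by income group.

Summarizes the recent-era setting-level measures as medians with
distribution-free 95% confidence intervals, globally and by World Bank
income group, and reports the economic-inequality contrast between low- and
middle-income settings.
"""

from _common import RESULTS, load_cells

from vaxineq.benchmark import benchmark
from vaxineq.measures import measures_frame


def main() -> None:
    _, cells, _ = load_cells()
    latest = [c for c in cells if 2014 <= c.year <= 2023]
    measures = measures_frame(latest)
    bench = benchmark(measures)
    bench.to_csv(RESULTS / "benchmark.csv", index=False)
    print(f"{len(bench)} benchmark rows -> results/benchmark.csv")

    rows = bench[
        (bench["indicator_id"] == "dtp3")
        & (bench["dimension_id"] == "wealth")
        & (bench["measure"] == "difference")
    ]
    print("\nDTP3 richest-poorest difference, median (95% CI) by group:")
    for _, r in rows.iterrows():
        print(
            f"  {r['group_value']:>13}: {r['median']:5.1f} pp "
            f"({r['ci_low']:.1f}, {r['ci_high']:.1f}), n={r['n_settings']}"
        )


if __name__ == "__main__":
    main()
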