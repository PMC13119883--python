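"""Change in inequality over the decade.

Pairs each setting's latest recent-era survey (2014-2023) with the older-era
survey (2004-2013) closest to ten years earlier, converts measure changes to
a per-decade scale, and drops indicator-dimension cells observed in fewer
than five settings.
"""

from _common import RESULTS, load_cells

from vaxineq.measures import measures_frame
from vaxineq.trends import pair_surveys, trend_cell_gate, trend_frame


def main() -> None:
    _, cells, _ = load_cells()
    measures = measures_frame(cells)

    years: dict[tuple, set] = {}
    for c in cells:
        years.setdefault((c.setting_id, c.indicator_id), set()).add(c.year)
    pairs, unpaired = pair_surveys({k: sorted(v) for k, v in years.items()})
    print(f"{len(pairs)} (setting, indicator) survey pairs; {len(unpaired)} unpairable")

    trends = trend_frame(measures, pairs)
    trends, dropped = trend_cell_gate(trends, min_settings=5)
    trends.to_csv(RESULTS / "trends.csv", index=False)
    dropped.to_csv(RESULTS / "trend_exclusions.csv", index=False)
    if not dropped.empty:
        gone = ", ".join(
            f"{r.indicator_id}/{r.dimension_id} (n={r.n_settings})"
            for r in dropped.itertuples()
        )
        print(f"excluded sparse trend cells: {gone}")

    med = (
        trends[trends["measure"] == "difference"]
        .groupby(["indicator_id", "dimension_id"])["change_per_decade"]
        .median()
    )
    print("\nmedian change in difference over 10 years (pp):")
    for dim in ("education", "wealth", "residence"):
        print(f"  DTP3, {dim}: {med.loc[('dtp3', dim)]:+.2f}")


if __name__ == "__main__":
    main()
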