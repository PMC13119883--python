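"""Latest situation of inequality.

Restricts the panel to the recent era (2014-2023), computes the five summary
measures per setting, the cross-country percentile table of national levels,
and the per-subgroup range of DTP3 coverage across settings.
"""

from _common import RESULTS, load_cells

from vaxineq.benchmark import national_percentile_table, subgroup_range
from vaxineq.measures import measures_frame
from vaxineq.plots import plot_subgroup_range


def main() -> None:
    _, cells, exclusions = load_cells()
    latest = [c for c in cells if 2014 <= c.year <= 2023]
    print(f"{len(latest)} complete recent-era cells ({len(exclusions)} excluded)")

    measures = measures_frame(latest)
    measures.to_csv(RESULTS / "measures_latest.csv", index=False)

    levels = national_percentile_table(cells)
    levels.to_csv(RESULTS / "national_levels.csv", index=False)
    print("\nnational levels across settings (%):")
    print(levels.to_string(index=False, float_format="%.1f"))

    for dim in ("wealth", "education"):
        sel = [c for c in latest if c.indicator_id == "dtp3" and c.dimension_id == dim]
        ranges = subgroup_range(sel)
        ranges.to_csv(RESULTS / f"dtp3_{dim}_subgroup_range.csv", index=False)
        plot_subgroup_range(
            ranges,
            title=f"DTP3 coverage by {dim} across settings",
            path=RESULTS / f"dtp3_{dim}_subgroup_range.svg",
        )
        print(f"\nDTP3 by {dim}: median coverage per subgroup across settings")
        print(ranges[["subgroup_id", "n_settings", "median", "iqr"]].to_string(
            index=False, float_format="%.1f"))

    med = (
        measures[measures["applicable"]]
        .groupby(["indicator_id", "dimension_id", "measure"])["value"]
        .median()
    )
    print("\nmedian education difference, DTP3: "
          f"{med.loc[('dtp3', 'education', 'difference')]:.1f} pp")
    print("median wealth SII (logit), DTP3: "
          f"{med.loc[('dtp3', 'wealth', 'sii')]:.1f} pp")


if __name__ == "__main__":
    main()
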