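"""Pipeline orchestration and report assembly.

`run_pipeline` takes hut-night records (read from CSV or freshly
simulated), produces the summary table, killing-effect tables under both
formula variants, the rank-based tests with their compact-letter
annotations, and per-day kill series; everything is recomputed through
the library modules so the report never contains report-only arithmetic.

`reproduce_published_numbers` re-derives the headline percentages of the
source trial report from its printed arm totals and tabulates them next
to the printed values, flagging any derived value more than half a
percentage point from print.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import endpoints, inference, published
from .endpoints import ArmSummary, killing_effects_frame
from .records import HutNightRecord, records_to_frame


@dataclass
class ReportBundle:
    summaries: dict[str, ArmSummary]
    summary_table: pd.DataFrame
    killing_effects: dict[str, pd.DataFrame]  # variant -> table
    tests: dict[str, inference.TestResult]  # metric -> Kruskal-Wallis
    pairwise: dict[str, list[inference.PairwiseResult]]
    letters: dict[str, dict[str, str]]  # metric -> group -> letters
    head_to_head: pd.DataFrame  # candidate vs each arm, rank-sum
    daily_deaths: pd.DataFrame  # night x arm kill totals
    params_log: dict = field(default_factory=dict)


def _per_hut_night(df: pd.DataFrame, value_cols: Sequence[str]) -> pd.DataFrame:
    g = df.groupby(["arm", "night", "hut"], as_index=False)[list(value_cols)].sum()
    return g


def run_pipeline(
    records: Sequence[HutNightRecord],
    species_group: str | None = "an_gambiae",
    alpha: float = 0.05,
    variant: str = "control_adjusted",
    candidate_arm: str = published.CANDIDATE_ARM,
    untreated_arm: str = published.UNTREATED_ARM,
    arm_order: Sequence[str] | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Run the full endpoint + inference analysis over records.

    With fewer than two arms the killing-effect tables are empty and the
    group tests are skipped (there is nothing to compare). When
    ``out_dir`` is given, all tables plus a plain-text report are
    written there deterministically.
    """
    df = records_to_frame(records)
    if species_group is not None:
        df = df[df["species_group"] == species_group]
    if df.empty:
        raise endpoints.EmptyDataError(
            f"no records for species_group {species_group!r}"
        )
    arms = list(arm_order) if arm_order else list(dict.fromkeys(df["arm"]))

    summaries = {
        a: endpoints.summarize_arm(records, a, species_group) for a in arms
    }
    summary_tbl = endpoints.summary_table(summaries)

    reference_arms = [a for a in arms if a not in (candidate_arm, untreated_arm)]
    ke_tables = {}
    for var in endpoints.VARIANTS:
        if candidate_arm in summaries and reference_arms and (
            var == "methods" or untreated_arm in summaries
        ):
            effects = endpoints.killing_effect_table(
                summaries,
                candidate_arm,
                reference_arms,
                untreated_arm=untreated_arm,
                variant=var,
            )
        else:
            effects = []
        ke_tables[var] = killing_effects_frame(effects)

    df = df.assign(
        entry=df[
            ["trapped", "dead_untrapped", "alive_delayed_dead", "alive_survived"]
        ].sum(axis=1),
        death=df[["trapped", "dead_untrapped", "alive_delayed_dead"]].sum(axis=1),
    )
    per_hn = _per_hut_night(df, ["entry", "death"])

    tests: dict[str, inference.TestResult] = {}
    pairwise: dict[str, list[inference.PairwiseResult]] = {}
    letters: dict[str, dict[str, str]] = {}
    if len(arms) >= 2:
        for metric in ("entry", "death"):
            samples = {
                a: per_hn.loc[per_hn["arm"] == a, metric].to_list()
                for a in arms
            }
            tests[metric] = inference.kruskal_wallis(samples)
            pairwise[metric] = inference.conover_iman(samples, alpha=alpha)
            letters[metric] = inference.compact_letter_display(pairwise[metric])

    h2h_rows = []
    if candidate_arm in arms:
        cand = per_hn.loc[per_hn["arm"] == candidate_arm, "death"].to_list()
        for other in arms:
            if other == candidate_arm:
                continue
            res = inference.rank_sum_test(
                cand, per_hn.loc[per_hn["arm"] == other, "death"].to_list()
            )
            h2h_rows.append(
                {
                    "candidate_arm": candidate_arm,
                    "other_arm": other,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.p_value < alpha,
                }
            )
    head_to_head = pd.DataFrame(
        h2h_rows,
        columns=["candidate_arm", "other_arm", "statistic", "p_value",
                 "significant"],
    )

    daily = (
        df.groupby(["night", "arm"], as_index=False)["death"]
        .sum()
        .pivot(index="night", columns="arm", values="death")
        .fillna(0)
        .astype(int)
    )

    bundle = ReportBundle(
        summaries=summaries,
        summary_table=summary_tbl,
        killing_effects=ke_tables,
        tests=tests,
        pairwise=pairwise,
        letters=letters,
        head_to_head=head_to_head,
        daily_deaths=daily,
        params_log={
            "species_group": species_group,
            "alpha": alpha,
            "variant": variant,
            "candidate_arm": candidate_arm,
            "untreated_arm": untreated_arm,
        },
    )
    if out_dir is not None:
        write_report(bundle, out_dir)
    return bundle


def _letters_frame(bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    for metric, letts in bundle.letters.items():
        for group, ls in letts.items():
            s = bundle.summaries[group]
            mean = s.mean_daily_entry if metric == "entry" else s.mean_daily_death
            sd = s.sd_daily_entry if metric == "entry" else s.sd_daily_death
            rows.append(
                {
                    "metric": metric,
                    "arm": group,
                    "n": s.n_hut_nights,
                    "mean_daily": round(mean, 1),
                    "sd_daily": round(sd, 1),
                    "letters": ls,
                }
            )
    return pd.DataFrame(
        rows, columns=["metric", "arm", "n", "mean_daily", "sd_daily", "letters"]
    )


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.summary_table.to_csv(out / "arm_summaries.csv", index=False)
    for variant, tbl in bundle.killing_effects.items():
        tbl.to_csv(out / f"killing_effects_{variant}.csv", index=False)
    _letters_frame(bundle).to_csv(out / "significance_letters.csv", index=False)
    bundle.head_to_head.to_csv(out / "head_to_head.csv", index=False)
    bundle.daily_deaths.to_csv(out / "daily_deaths.csv")

    lines = ["Hut-trial analysis report", "=" * 26, ""]
    lines.append(f"parameters: {bundle.params_log}")
    lines.append("")
    lines.append("Arm summaries (per hut-night):")
    lines.append(bundle.summary_table.to_string(index=False))
    for variant, tbl in bundle.killing_effects.items():
        lines.append("")
        lines.append(f"Increased killing effect ({variant} variant):")
        lines.append(tbl.to_string(index=False) if len(tbl) else "  (no reference arms)")
    for metric, res in bundle.tests.items():
        lines.append("")
        lines.append(
            f"Kruskal-Wallis on daily {metric}: H={res.statistic:.3f}, "
            f"p={res.p_value:.4g}"
        )
        lines.append(f"letters: {bundle.letters[metric]}")
    if len(bundle.head_to_head):
        lines.append("")
        lines.append("Candidate vs each arm (rank-sum on daily kills):")
        lines.append(bundle.head_to_head.to_string(index=False))
    (out / "report.txt").write_text("\n".join(lines) + "\n")


def reproduce_published_numbers() -> pd.DataFrame:
    """Re-derive the report's headline percentages from its printed totals.

    Returns a table with the computed value, the printed value, their
    absolute difference, and a MISMATCH flag for differences above half
    a percentage point (the Methods-variant killing effects carry this
    flag: the printed values were evidently produced with the
    control-normalised formula of the figure caption).
    """
    sums = published.published_summaries()
    rows: list[dict] = []

    def add(quantity: str, computed: float, printed: float) -> None:
        diff = abs(computed - printed)
        rows.append(
            {
                "quantity": quantity,
                "computed": round(computed, 2),
                "printed": printed,
                "abs_diff": round(diff, 2),
                "flag": "MISMATCH" if diff > 0.5 else "",
            }
        )

    add(
        "T-LLIN An. gambiae mortality (%)",
        sums[published.CANDIDATE_ARM].mortality_pct,
        published.PRINTED_MORTALITY_TLLIN_PCT,
    )
    add(
        "untreated-control mortality (%)",
        sums[published.UNTREATED_ARM].mortality_pct,
        published.PRINTED_MORTALITY_UNTREATED_PCT,
    )
    add(
        "T-LLIN trap share of kills (%)",
        sums[published.CANDIDATE_ARM].trap_attributable_pct,
        published.PRINTED_TRAP_SHARE_PCT,
    )
    add(
        "other-species T-LLIN mortality (%)",
        100.0
        * published.OTHER_SPECIES_TLLIN_DEATH
        / published.OTHER_SPECIES_TLLIN_ENTRY,
        published.PRINTED_OTHER_MORTALITY_PCT,
    )
    add(
        "other-species trap share of kills (%)",
        100.0
        * published.OTHER_SPECIES_TLLIN_TRAPPED
        / published.OTHER_SPECIES_TLLIN_DEATH,
        published.PRINTED_OTHER_TRAP_SHARE_PCT,
    )
    add(
        "An. gambiae share of total catch (%)",
        100.0 * published.TOTAL_AN_GAMBIAE / published.TOTAL_ALL_SPECIES,
        published.PRINTED_AN_GAMBIAE_FRACTION_PCT,
    )
    for variant in ("control_adjusted", "methods"):
        effects = endpoints.killing_effect_table(
            sums,
            published.CANDIDATE_ARM,
            published.REFERENCE_ARMS,
            untreated_arm=published.UNTREATED_ARM,
            variant=variant,
        )
        for e in effects:
            add(
                f"killing effect vs {e.reference_arm} ({variant}) (%)",
                e.value_pct,
                published.PRINTED_KILLING_EFFECT_PCT[e.reference_arm],
            )
    return pd.DataFrame(rows)


def make_figures(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Optional per-arm daily-kill and killing-effect plots (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    cand = bundle.params_log.get("candidate_arm")
    daily = bundle.daily_deaths
    if cand in daily.columns:
        for other in [c for c in daily.columns if c != cand]:
            fig, ax = plt.subplots(figsize=(7, 3.5))
            ax.plot(daily.index, daily[cand], label=cand, lw=1.5)
            ax.plot(daily.index, daily[other], label=other, lw=1.5)
            ax.set_xlabel("night")
            ax.set_ylabel("mosquitoes killed")
            ax.legend()
            fig.tight_layout()
            path = out / f"daily_kills_{other.replace(' ', '_')}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)
    ke = bundle.killing_effects.get("control_adjusted")
    if ke is not None and len(ke):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(ke["reference_arm"], ke["value_pct"])
        ax.set_ylabel("increased killing effect (%)")
        fig.tight_layout()
        path = out / "killing_effect.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
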