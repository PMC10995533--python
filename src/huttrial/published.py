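"""Printed arm totals from the source hut-trial report.

These constants are the in-report worked example: the *An. gambiae*
entry/death totals of the report's summary table, the trap-compartment
kill counts, and the headline percentages printed in its results text.
They let the endpoint calculations be exercised against the published
values without the (unpublished) raw nightly data.

Each constant notes where in the report it is printed.
"""

from __future__ import annotations

from .endpoints import ArmSummary

CANDIDATE_ARM = "T-LLIN"
UNTREATED_ARM = "untreated"
REFERENCE_ARMS = ["PN2.0", "Tsara boost", "IG2"]
ARM_ORDER = ["IG2", "Tsara boost", "PN2.0", "T-LLIN", "untreated"]

# summary table: An. gambiae totals per arm over the six-week trial
TABLE_ENTRY = {
    "IG2": 611,
    "Tsara boost": 698,
    "PN2.0": 509,
    "T-LLIN": 760,
    "untreated": 450,
}
TABLE_DEATH = {
    "IG2": 535,
    "Tsara boost": 505,
    "PN2.0": 413,
    "T-LLIN": 678,
    "untreated": 118,
}
# summary table: printed daily SDs (entry, death) per arm
TABLE_SD_ENTRY = {
    "IG2": 11.5,
    "Tsara boost": 13.8,
    "PN2.0": 7.1,
    "T-LLIN": 10.6,
    "untreated": 6.6,
}
TABLE_SD_DEATH = {
    "IG2": 10.0,
    "Tsara boost": 6.7,
    "PN2.0": 6.0,
    "T-LLIN": 9.0,
    "untreated": 2.7,
}

# results text: An. gambiae caught in the T-LLIN trap compartment
TLLIN_TRAPPED = 317

# results text: all-species and other-species totals
TOTAL_ALL_SPECIES = 7835
TOTAL_AN_GAMBIAE = 3041
OTHER_SPECIES_TLLIN_ENTRY = 1150
OTHER_SPECIES_TLLIN_DEATH = 583
OTHER_SPECIES_TLLIN_TRAPPED = 323

# headline percentages as printed in the results text / figure
PRINTED_MORTALITY_TLLIN_PCT = 89.2          # 678 / 760
PRINTED_MORTALITY_UNTREATED_PCT = 26.2      # 118 / 450
PRINTED_TRAP_SHARE_PCT = 46.75              # 317 / 678
PRINTED_OTHER_MORTALITY_PCT = 50.7          # 583 / 1150
PRINTED_OTHER_TRAP_SHARE_PCT = 55.4         # 323 / 583
PRINTED_AN_GAMBIAE_FRACTION_PCT = 38.8      # 3041 / 7835
PRINTED_KILLING_EFFECT_PCT = {
    "PN2.0": 58.5,
    "Tsara boost": 38.0,
    "IG2": 31.5,
}

# trial dimensions: 5 arms x 2 replicate huts, ~34 nights -> 68 hut-nights/arm
N_HUT_NIGHTS_PER_ARM = 68

# grand mean An. gambiae entries per hut-night over the summary table
# (3028 tabulated entries / 340 hut-nights, about 8.9)
TOTAL_AN_GAMBIAE_TRIAL_MEAN = sum(TABLE_ENTRY.values()) / (
    5 * N_HUT_NIGHTS_PER_ARM
)


def published_summaries() -> dict[str, ArmSummary]:
    """Arm summaries reconstructed from the printed totals.

    Daily means are totals / 68 hut-nights; daily SDs are the printed
    values (the nightly data behind them are not published). Trap counts
    are known only for the candidate arm.
    """
    out = {}
    for arm in ARM_ORDER:
        entry = TABLE_ENTRY[arm]
        death = TABLE_DEATH[arm]
        trapped = TLLIN_TRAPPED if arm == CANDIDATE_ARM else 0
        out[arm] = ArmSummary(
            arm=arm,
            n_hut_nights=N_HUT_NIGHTS_PER_ARM,
            total_entry=entry,
            mean_daily_entry=entry / N_HUT_NIGHTS_PER_ARM,
            sd_daily_entry=TABLE_SD_ENTRY[arm],
            total_death=death,
            mean_daily_death=death / N_HUT_NIGHTS_PER_ARM,
            sd_daily_death=TABLE_SD_DEATH[arm],
            mortality_pct=100.0 * death / entry,
            trapped_total=trapped,
            trap_attributable_pct=100.0 * trapped / death,
        )
    return out
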