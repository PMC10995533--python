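"""Summary endpoints of the hut trial.

Mortality is defined operationally: a mosquito counts as killed if it was
found dead (immediately or after the 24-36 h holding period) *or* was
caught in the trap compartment — trapped mosquitoes are counted as dead
even when collected alive, because a trapped mosquito is removed from the
biting population just as surely.

The increased killing effect of the candidate trapping net over a
reference net comes in two printed variants that do not agree:

* ``methods`` variant, normalised by the reference arm's own catch::

      100 * (K_cand - K_ref) / T_ref

* ``control_adjusted`` variant (the default), normalised by the
  untreated-control catch; the control kill counts cancel algebraically::

      100 * [(K_cand - K_un) - (K_ref - K_un)] / T_un
    = 100 * (K_cand - K_ref) / T_un

where K is an arm's total kill count and T its total catch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import FateCounts, HutNightRecord, records_to_frame

VARIANTS = ("methods", "control_adjusted")


class EmptyDataError(ValueError):
    pass


def death_count(counts: FateCounts) -> int:
    """Mosquitoes scored as killed: trapped + dead + delayed dead."""
    return counts.trapped + counts.dead_untrapped + counts.alive_delayed_dead


@dataclass(frozen=True)
class ArmSummary:
    """One arm's row of the trial summary table."""

    arm: str
    n_hut_nights: int
    total_entry: int
    mean_daily_entry: float
    sd_daily_entry: float
    total_death: int
    mean_daily_death: float
    sd_daily_death: float
    mortality_pct: float
    trapped_total: int
    trap_attributable_pct: float


@dataclass(frozen=True)
class KillingEffect:
    candidate_arm: str
    reference_arm: str
    k_candidate: int
    k_reference: int
    t_reference: int | None
    k_untreated: int | None
    t_untreated: int | None
    variant: str
    value_pct: float


def summarize_arm(
    records: Sequence[HutNightRecord],
    arm: str,
    species_group: str | None = None,
) -> ArmSummary:
    """Summarise one arm over its hut-nights.

    Daily means and SDs are over hut-night totals (SD with denominator
    n-1); hut-nights with zero entries are real observation nights and
    must be present as zero-count records. ``mortality_pct`` is
    100 * total deaths / total entries and ``trap_attributable_pct`` is
    the share of deaths caught in the trap compartment (0 when there are
    no deaths).
    """
    rows = [
        r
        for r in records
        if r.arm == arm
        and (species_group is None or r.species_group == species_group)
    ]
    if not rows:
        raise EmptyDataError(
            f"no hut-nights for arm {arm!r}"
            + (f", species_group {species_group!r}" if species_group else "")
        )
    df = records_to_frame(rows)
    per_hn = df.groupby(["night", "hut"], as_index=False).agg(
        trapped=("trapped", "sum"),
        dead_untrapped=("dead_untrapped", "sum"),
        alive_delayed_dead=("alive_delayed_dead", "sum"),
        alive_survived=("alive_survived", "sum"),
    )
    entries = (
        per_hn[["trapped", "dead_untrapped", "alive_delayed_dead",
                "alive_survived"]].sum(axis=1).to_numpy(dtype=float)
    )
    deaths = (
        per_hn[["trapped", "dead_untrapped", "alive_delayed_dead"]]
        .sum(axis=1)
        .to_numpy(dtype=float)
    )
    n = len(per_hn)
    total_entry = int(entries.sum())
    total_death = int(deaths.sum())
    trapped_total = int(per_hn["trapped"].sum())
    return ArmSummary(
        arm=arm,
        n_hut_nights=n,
        total_entry=total_entry,
        mean_daily_entry=total_entry / n,
        sd_daily_entry=float(np.std(entries, ddof=1)) if n > 1 else 0.0,
        total_death=total_death,
        mean_daily_death=total_death / n,
        sd_daily_death=float(np.std(deaths, ddof=1)) if n > 1 else 0.0,
        mortality_pct=100.0 * total_death / total_entry if total_entry else 0.0,
        trapped_total=trapped_total,
        trap_attributable_pct=(
            100.0 * trapped_total / total_death if total_death else 0.0
        ),
    )


def summarize_arms(
    records: Sequence[HutNightRecord],
    arms: Iterable[str],
    species_group: str | None = None,
) -> dict[str, ArmSummary]:
    return {a: summarize_arm(records, a, species_group) for a in arms}


def summary_table(summaries: Mapping[str, ArmSummary]) -> pd.DataFrame:
    """Summary-table frame mirroring the trial report's layout."""
    return pd.DataFrame(
        [
            {
                "arm": s.arm,
                "n_hut_nights": s.n_hut_nights,
                "total_entry": s.total_entry,
                "mean_daily_entry": round(s.mean_daily_entry, 1),
                "sd_daily_entry": round(s.sd_daily_entry, 1),
                "total_death": s.total_death,
                "mean_daily_death": round(s.mean_daily_death, 1),
                "sd_daily_death": round(s.sd_daily_death, 1),
                "mortality_pct": round(s.mortality_pct, 1),
                "trapped_total": s.trapped_total,
                "trap_attributable_pct": round(s.trap_attributable_pct, 1),
            }
            for s in summaries.values()
        ]
    )


def killing_effect_methods(
    k_candidate: int,
    k_reference: int,
    t_reference: int,
    candidate_arm: str = "candidate",
    reference_arm: str = "reference",
) -> KillingEffect:
    """Killing effect normalised by the reference arm's catch."""
    if t_reference <= 0:
        raise ZeroDivisionError("t_reference must be > 0")
    value = 100.0 * (k_candidate - k_reference) / t_reference
    return KillingEffect(
        candidate_arm=candidate_arm,
        reference_arm=reference_arm,
        k_candidate=k_candidate,
        k_reference=k_reference,
        t_reference=t_reference,
        k_untreated=None,
        t_untreated=None,
        variant="methods",
        value_pct=value,
    )


def killing_effect_control_adjusted(
    k_candidate: int,
    k_reference: int,
    k_untreated: int,
    t_untreated: int,
    candidate_arm: str = "candidate",
    reference_arm: str = "reference",
) -> KillingEffect:
    """Killing effect normalised by the untreated-control catch.

    The control kill count ``k_untreated`` cancels algebraically but is
    retained in the result for traceability.
    """
    if t_untreated <= 0:
        raise ZeroDivisionError("t_untreated must be > 0")
    value = (
        100.0
        * ((k_candidate - k_untreated) - (k_reference - k_untreated))
        / t_untreated
    )
    return KillingEffect(
        candidate_arm=candidate_arm,
        reference_arm=reference_arm,
        k_candidate=k_candidate,
        k_reference=k_reference,
        t_reference=None,
        k_untreated=k_untreated,
        t_untreated=t_untreated,
        variant="control_adjusted",
        value_pct=value,
    )


def killing_effect_table(
    summaries: Mapping[str, ArmSummary],
    candidate_arm: str,
    reference_arms: Sequence[str],
    untreated_arm: str | None = None,
    variant: str = "control_adjusted",
) -> list[KillingEffect]:
    """One killing effect per reference arm, from arm summaries.

    Uses each arm's total deaths as K and total entries as T. The
    ``control_adjusted`` variant requires ``untreated_arm``.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    for name in [candidate_arm, *reference_arms]:
        if name not in summaries:
            raise KeyError(f"arm {name!r} not summarized")
    cand = summaries[candidate_arm]
    out = []
    for ref in reference_arms:
        s = summaries[ref]
        if variant == "methods":
            out.append(
                killing_effect_methods(
                    cand.total_death,
                    s.total_death,
                    s.total_entry,
                    candidate_arm=candidate_arm,
                    reference_arm=ref,
                )
            )
        else:
            if untreated_arm is None or untreated_arm not in summaries:
                raise KeyError(
                    "control_adjusted variant needs a summarized untreated arm"
                )
            un = summaries[untreated_arm]
            out.append(
                killing_effect_control_adjusted(
                    cand.total_death,
                    s.total_death,
                    un.total_death,
                    un.total_entry,
                    candidate_arm=candidate_arm,
                    reference_arm=ref,
                )
            )
    return out


def killing_effects_frame(effects: Sequence[KillingEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "candidate_arm": e.candidate_arm,
                "reference_arm": e.reference_arm,
                "variant": e.variant,
                "k_candidate": e.k_candidate,
                "k_reference": e.k_reference,
                "t_reference": e.t_reference,
                "k_untreated": e.k_untreated,
                "t_untreated": e.t_untreated,
                "value_pct": round(e.value_pct, 2),
            }
            for e in effects
        ]
    )
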