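"""Rotation design for experimental hut trials.

An experimental hut trial assigns treatment arms (bednets) to huts and
volunteer sleepers to huts night by night. To balance hut and sleeper
effects across arms, sleepers rotate daily by a cyclic shift while the
physical nets rotate between huts every ``net_rotation_period_nights``
nights (default 3) following a randomized Latin square, so that over a
full cycle each net visits each hut at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

TREATMENT_CLASSES = frozenset(
    {"untreated", "pyrethroid", "pyrethroid+PBO", "pyrethroid+pyrrole"}
)


class DesignError(ValueError):
    """Raised for inconsistent design configurations."""


@dataclass(frozen=True)
class Arm:
    """One treatment arm of the trial.

    Parameters
    ----------
    name : str
        Short unique label, e.g. ``"T-LLIN"``.
    treatment_class : str
        One of ``untreated``, ``pyrethroid``, ``pyrethroid+PBO``,
        ``pyrethroid+pyrrole``.
    has_trap_compartment : bool
        Whether the net carries an insecticide-free trap compartment on
        its roof.
    n_replicate_nets : int
        Number of physical net instances (and hence huts occupied each
        night) for this arm.
    """

    name: str
    treatment_class: str
    has_trap_compartment: bool = False
    n_replicate_nets: int = 1

    def __post_init__(self) -> None:
        if self.treatment_class not in TREATMENT_CLASSES:
            raise DesignError(
                f"unknown treatment_class {self.treatment_class!r}; "
                f"expected one of {sorted(TREATMENT_CLASSES)}"
            )
        if self.n_replicate_nets < 1:
            raise DesignError("n_replicate_nets must be >= 1")


@dataclass
class TrialDesign:
    """A fully scheduled trial.

    ``schedule`` has one row per (night, hut) with 1-based ``night``,
    ``hut`` and ``sleeper`` indices, the ``arm`` name and the physical
    ``net_id`` occupying the hut that night.
    """

    arms: list[Arm]
    n_huts: int
    n_sleepers: int
    n_nights: int
    net_rotation_period_nights: int = 3
    schedule: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def arm_names(self) -> list[str]:
        return [a.name for a in self.arms]

    def arm(self, name: str) -> Arm:
        for a in self.arms:
            if a.name == name:
                return a
        raise KeyError(f"no arm named {name!r}")

    def hut_nights_per_arm(self) -> dict[str, int]:
        """Number of hut-nights each arm is observed."""
        return self.schedule.groupby("arm").size().to_dict()


def latin_square(n: int, seed: int) -> np.ndarray:
    """Random ``n`` x ``n`` Latin square over symbols ``0..n-1``.

    Starts from the cyclic square ``L[i, j] = (i + j) mod n`` and applies
    independent random row, column and symbol permutations, which keeps
    the Latin property. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("latin square order must be >= 1")
    rng = np.random.default_rng(seed)
    base = (np.arange(n)[:, None] + np.arange(n)[None, :]) % n
    rows = rng.permutation(n)
    cols = rng.permutation(n)
    symbols = rng.permutation(n)
    return symbols[base[np.ix_(rows, cols)]]


def build_schedule(
    arms: list[Arm],
    n_huts: int,
    n_sleepers: int,
    n_nights: int,
    net_rotation_period_nights: int = 3,
    seed: int = 0,
) -> TrialDesign:
    """Build the full rotation schedule.

    Net instances are laid out per arm (``"<arm>#1"``, ``"<arm>#2"``, ...)
    and rotated between huts via a randomized Latin square whose rows are
    rotation blocks of ``net_rotation_period_nights`` nights; sleepers
    advance one hut per night by a cyclic shift. An incomplete final
    block is truncated at ``n_nights``.
    """
    names = [a.name for a in arms]
    if len(set(names)) != len(names):
        raise DesignError("arm names must be unique")
    total_nets = sum(a.n_replicate_nets for a in arms)
    if total_nets != n_huts:
        raise DesignError(
            f"replicate nets sum to {total_nets} but the design has "
            f"{n_huts} huts"
        )
    if n_sleepers != n_huts:
        raise DesignError("need exactly one sleeper per hut")
    if n_nights < 1 or net_rotation_period_nights < 1:
        raise DesignError("n_nights and rotation period must be >= 1")

    net_ids = [
        f"{a.name}#{i + 1}" for a in arms for i in range(a.n_replicate_nets)
    ]
    net_arm = {
        f"{a.name}#{i + 1}": a.name
        for a in arms
        for i in range(a.n_replicate_nets)
    }
    square = latin_square(n_huts, seed)

    rows = []
    for night in range(1, n_nights + 1):
        block = (night - 1) // net_rotation_period_nights
        for hut in range(1, n_huts + 1):
            net = net_ids[square[block % n_huts, hut - 1]]
            sleeper = (hut - 1 + (night - 1)) % n_sleepers + 1
            rows.append(
                {
                    "night": night,
                    "hut": hut,
                    "sleeper": sleeper,
                    "arm": net_arm[net],
                    "net_id": net,
                }
            )
    schedule = pd.DataFrame(rows)
    return TrialDesign(
        arms=list(arms),
        n_huts=n_huts,
        n_sleepers=n_sleepers,
        n_nights=n_nights,
        net_rotation_period_nights=net_rotation_period_nights,
        schedule=schedule,
    )


def validate_schedule(design: TrialDesign) -> list[str]:
    """Check every design invariant; return human-readable violations.

    Never raises: an empty list means the schedule is valid. Each
    violation names the night (or net) and the broken constraint.
    """
    v: list[str] = []
    sched = design.schedule
    if sched.empty:
        return ["schedule is empty"]
    period = design.net_rotation_period_nights
    huts = set(range(1, design.n_huts + 1))
    sleepers = set(range(1, design.n_sleepers + 1))
    known_arms = set(design.arm_names)

    for night, grp in sched.groupby("night"):
        night = int(night)
        hut_counts = grp["hut"].value_counts()
        if set(grp["hut"]) != huts or (hut_counts != 1).any():
            v.append(
                f"night {night}: huts occupied {sorted(set(grp['hut']))} "
                f"!= one row per hut {sorted(huts)}"
            )
        if sorted(grp["sleeper"]) != sorted(sleepers):
            v.append(
                f"night {night}: sleepers {sorted(grp['sleeper'])} are not "
                "a permutation of all sleepers"
            )
        bad_arms = set(grp["arm"]) - known_arms
        if bad_arms:
            v.append(f"night {night}: unknown arms {sorted(bad_arms)}")

    # arm layout may change only at block boundaries
    pivot = sched.pivot_table(
        index="night", columns="hut", values="arm", aggfunc="first"
    ).sort_index()
    for night in pivot.index[1:]:
        if (night - 1) % period == 0:
            continue
        if not pivot.loc[night].equals(pivot.loc[night - 1]):
            v.append(
                f"night {int(night)}: net layout changed inside a "
                f"{period}-night rotation block"
            )

    # rotation coverage per physical net over each full cycle
    if "net_id" in sched.columns:
        cycle_nights = period * design.n_huts
        blocks = sched.assign(cycle=(sched["night"] - 1) // cycle_nights)
        for (net, cycle), grp in blocks.groupby(["net_id", "cycle"]):
            hut_blocks = grp.drop_duplicates(["hut"])
            n_blocks = grp["night"].apply(
                lambda x: (x - 1) // period
            ).nunique()
            if hut_blocks.shape[0] < n_blocks:
                v.append(
                    f"net {net}, cycle {int(cycle)}: revisits a hut before "
                    "completing the rotation cycle"
                )
    else:
        # arm-level fallback: an arm glued to one hut for > period nights
        # per replicate cannot be a valid rotation
        for arm, grp in sched.groupby("arm"):
            reps = design.arm(str(arm)).n_replicate_nets
            per_hut = grp.groupby("hut").size()
            cycles = max(1, -(-design.n_nights // (period * design.n_huts)))
            if (per_hut > period * reps * cycles).any():
                v.append(
                    f"arm {arm}: occupies a single hut longer than the "
                    "rotation allows (net never moves)"
                )
    return v


def write_schedule(design: TrialDesign, path) -> None:
    """Export the schedule as CSV with columns night,hut,sleeper,arm."""
    design.schedule[["night", "hut", "sleeper", "arm"]].to_csv(
        path, index=False
    )


def read_schedule(path) -> pd.DataFrame:
    """Read a night,hut,sleeper,arm schedule CSV."""
    df = pd.read_csv(path)
    required = ["night", "hut", "sleeper", "arm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DesignError(f"schedule file misses columns {missing}")
    return df


def arms_from_config(cfg: dict) -> list[Arm]:
    return [
        Arm(
            name=a["name"],
            treatment_class=a["treatment_class"],
            has_trap_compartment=bool(a.get("has_trap_compartment", False)),
            n_replicate_nets=int(a.get("n_replicate_nets", 1)),
        )
        for a in cfg["arms"]
    ]


def design_from_config(cfg: dict, seed: int | None = None) -> TrialDesign:
    """Build a design from a config mapping (e.g. parsed YAML).

    Keys: ``arms`` (list of arm mappings), ``n_huts``, ``n_sleepers``,
    ``n_nights``, ``net_rotation_period_nights``, ``seed``.
    """
    arms = arms_from_config(cfg)
    return build_schedule(
        arms,
        n_huts=int(cfg["n_huts"]),
        n_sleepers=int(cfg["n_sleepers"]),
        n_nights=int(cfg["n_nights"]),
        net_rotation_period_nights=int(cfg.get("net_rotation_period_nights", 3)),
        seed=int(cfg["seed"] if seed is None else seed),
    )


def load_design_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
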