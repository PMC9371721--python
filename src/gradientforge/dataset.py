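"""Batch sampling of the {E_appl, (P, D, L)} condition space and dataset IO.

The surrogate is trained on tables of simulated gradient profiles: each row
holds the four condition inputs plus the 20-point laterally averaged profile.
Conditions are drawn uniformly and independently over the applied-potential
window and the morphology block, with draws violating the geometric
constraint D < P rejected and redrawn.  The production dataset size is
10,000 rows per species; any smaller ``n`` yields a scaled-down set under
the same protocol.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .geometry import MORPHOLOGY_BOUNDS, Morphology
from .physchem import DEFAULT_POTENTIAL_WINDOW, CatalystKinetics, load_catalyst
from .solver import PROFILE_Z_UM, SolverError, SolverSettings, simulate

__all__ = [
    "ConditionSample",
    "GradientDataset",
    "DEFAULT_RANGES",
    "sample_conditions",
    "generate_dataset",
    "PROFILE_COLUMNS",
    "INPUT_COLUMNS",
]

log = logging.getLogger(__name__)

#: sampling ranges: potential window (V vs RHE) + morphology block (um)
DEFAULT_RANGES = {
    "E_appl": DEFAULT_POTENTIAL_WINDOW,
    "P": MORPHOLOGY_BOUNDS["P"],
    "D": MORPHOLOGY_BOUNDS["D"],
    "L": MORPHOLOGY_BOUNDS["L"],
}

INPUT_COLUMNS = ["E_appl_V", "P_um", "D_um", "L_um"]
PROFILE_COLUMNS = [f"c_z{int(z):03d}" for z in PROFILE_Z_UM]


@dataclass(frozen=True)
class ConditionSample:
    """One simulation condition with its RNG provenance."""

    E_appl: float
    morph: Morphology
    seed: int
    index: int


@dataclass
class GradientDataset:
    """Table of (condition inputs, 20-point profile in mM) rows plus metadata."""

    species: str
    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = INPUT_COLUMNS + PROFILE_COLUMNS
        if list(self.frame.columns) != expected:
            raise ValueError(f"dataset must have exactly the columns {expected}")
        if self.frame.isna().any().any():
            raise ValueError("dataset contains NaN values")
        if (self.frame[PROFILE_COLUMNS].to_numpy() < 0).any():
            raise ValueError("negative concentrations in dataset")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """Condition inputs (N, 4): E_appl, P, D, L."""
        return self.frame[INPUT_COLUMNS].to_numpy()

    @property
    def Y(self) -> np.ndarray:
        """Profile targets (N, 20), mM."""
        return self.frame[PROFILE_COLUMNS].to_numpy()

    def write_csv(self, path) -> None:
        """Write the table as CSV plus a JSON metadata sidecar."""
        self.frame.to_csv(path, index=False)
        sidecar = str(path) + ".meta.json"
        with open(sidecar, "w") as fh:
            json.dump({"species": self.species, **self.metadata}, fh, indent=2)

    @classmethod
    def read_csv(cls, path, species: str | None = None) -> "GradientDataset":
        # round_trip parsing keeps write->read->write byte-identical
        frame = pd.read_csv(path, float_precision="round_trip")
        metadata: dict = {}
        try:
            with open(str(path) + ".meta.json") as fh:
                metadata = json.load(fh)
        except FileNotFoundError:
            pass
        sp = species or metadata.get("species")
        if sp is None:
            raise ValueError("species not given and no metadata sidecar found")
        metadata.pop("species", None)
        return cls(species=sp, frame=frame, metadata=metadata)

    def subset(self, indices) -> "GradientDataset":
        return GradientDataset(
            species=self.species,
            frame=self.frame.iloc[np.asarray(indices)].reset_index(drop=True),
            metadata=dict(self.metadata),
        )


def sample_conditions(
    n: int, seed: int, ranges: dict | None = None
) -> list[ConditionSample]:
    """Draw ``n`` independent uniform conditions; redraw any with D >= P.

    Identical (n, seed, ranges) reproduce the identical list.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    d_lo, p_hi = ranges["D"][0], ranges["P"][1]
    if d_lo >= p_hi:
        raise ValueError("empty feasible region: min D >= max P")
    rng = np.random.default_rng(seed)

    def draw(m: int) -> np.ndarray:
        cols = [rng.uniform(*ranges[k], size=m) for k in ("E_appl", "P", "D", "L")]
        return np.column_stack(cols)

    rows = draw(n)
    bad = rows[:, 2] >= rows[:, 1]
    while bad.any():
        rows[bad] = draw(int(bad.sum()))
        bad = rows[:, 2] >= rows[:, 1]
    return [
        ConditionSample(E_appl=float(r[0]), morph=Morphology(*r[1:4]), seed=seed, index=i)
        for i, r in enumerate(rows)
    ]


def generate_dataset(
    samples: list[ConditionSample],
    catalyst: str | CatalystKinetics,
    settings: SolverSettings | None = None,
    workers: int = 1,
    max_failure_fraction: float = 0.01,
) -> dict[str, GradientDataset]:
    """Run the simulator over all samples and tabulate per-species datasets.

    Returns ``{"O2": ds}`` for 4e-only catalysts (Pt) and additionally
    ``"H2O2"`` for peroxide-producing ones (Au).  Row order follows sample
    order regardless of parallel execution; failed solves are logged and
    excluded, and more than ``max_failure_fraction`` failures aborts the run.
    """
    settings = settings or SolverSettings()
    kin = load_catalyst(catalyst) if isinstance(catalyst, str) else catalyst

    def run_one(s: ConditionSample):
        try:
            return simulate(s.morph, kin, s.E_appl, settings)
        except (SolverError, ValueError) as exc:
            return exc

    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers)(delayed(run_one)(s) for s in samples)
    else:
        results = [run_one(s) for s in samples]

    rows_o2, rows_h2o2, failures = [], [], []
    for s, res in zip(samples, results):
        if isinstance(res, Exception):
            failures.append((s.index, str(res)))
            log.warning("solve failed for sample %d (%s): %s", s.index, s.morph, res)
            continue
        o2, h2o2 = res
        inputs = [s.E_appl, s.morph.P, s.morph.D, s.morph.L]
        rows_o2.append(inputs + list(o2.c_mM))
        if kin.has_peroxide_channel:
            rows_h2o2.append(inputs + list(h2o2.c_mM))

    if len(failures) > max_failure_fraction * len(samples):
        raise RuntimeError(
            f"{len(failures)}/{len(samples)} solver failures exceed the "
            f"{max_failure_fraction:.0%} limit; first: {failures[:3]}"
        )

    meta = {
        "catalyst": kin.name,
        "seed": samples[0].seed if samples else None,
        "n_requested": len(samples),
        "n_failed": len(failures),
        "failures": failures,
        "solver": {
            "mode": settings.mode,
            "spacing_um": settings.spacing_um,
            "include_base": settings.include_base,
        },
        "code_version": _pkg_version,
    }
    cols = INPUT_COLUMNS + PROFILE_COLUMNS
    out = {"O2": GradientDataset("O2", pd.DataFrame(rows_o2, columns=cols), dict(meta))}
    if kin.has_peroxide_channel:
        out["H2O2"] = GradientDataset("H2O2", pd.DataFrame(rows_h2o2, columns=cols), dict(meta))
    return out
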