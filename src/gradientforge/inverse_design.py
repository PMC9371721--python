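"""Similarity-score search of the morphology space against a target gradient.

A target is a handful of anchor concentrations at fixed heights (seven
anchors by default, species-specific) plus the applied potential the design
must operate at.  Candidate morphologies are drawn uniformly from the design
block, their profiles predicted with the trained surrogate, and ranked by
the similarity score

    S = 1 - (1/|C|) * sum_{z in C} |c_pred(z) - c_target(z)| / c_target(z),

i.e. one minus the mean relative error over the anchor set: S = 1 for a
perfect match, S = 0.9 for a uniform 10% error.  S is kept as an unclamped
fraction (wildly wrong profiles can score below zero) and rendered as a
percentage only in reports.  The top 10,000 scorers are retained and can be
aggregated into sliced (P, D) score maps per wire-length band.

``verify_design`` closes the loop: the winning morphology is re-simulated
with the full solver (not the surrogate) and compared against the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DEFAULT_RANGES
from .geometry import Morphology
from .physchem import CatalystKinetics
from .solver import GradientProfile, SolverSettings, simulate
from .surrogate import SurrogateModel

__all__ = [
    "ANCHOR_Z_O2",
    "ANCHOR_Z_H2O2",
    "DEFAULT_L_BANDS",
    "TargetProfile",
    "DesignResult",
    "similarity_score",
    "search_morphologies",
    "slice_score_map",
    "verify_design",
]

#: anchor heights (um) scoring O2 and H2O2 targets.
ANCHOR_Z_O2 = (5.0, 10.0, 15.0, 25.0, 35.0, 45.0, 70.0)
ANCHOR_Z_H2O2 = (5.0, 20.0, 30.0, 40.0, 55.0, 70.0, 80.0)

#: L-band slices for score maps: label (um) -> [lo, hi) range (um).
DEFAULT_L_BANDS = {
    5.0: (0.0, 10.0),
    20.0: (10.0, 30.0),
    40.0: (30.0, 50.0),
    60.0: (50.0, 70.0),
    80.0: (70.0, 90.0),
    95.0: (90.0, 100.0),
}

#: at most this many candidates are retained by the search.
MAX_RETAINED = 10_000


@dataclass(frozen=True)
class TargetProfile:
    """Desired gradient: anchor (z, c) pairs at a fixed applied potential."""

    species: str
    E_appl: float
    anchors_z: tuple[float, ...]
    anchors_c: tuple[float, ...]  # mM

    def __post_init__(self) -> None:
        if len(self.anchors_z) != len(self.anchors_c) or not self.anchors_z:
            raise ValueError("anchors_z and anchors_c must be equal-length, non-empty")
        if any(c <= 0 for c in self.anchors_c):
            raise ValueError(
                "target concentrations must be > 0 at every anchor "
                "(relative error is undefined at zero)"
            )

    @classmethod
    def from_profile(
        cls, profile: GradientProfile, E_appl: float,
        anchors_z: tuple[float, ...] | None = None,
    ) -> "TargetProfile":
        """Anchor a target on a simulated/predicted profile (closed-loop use)."""
        if anchors_z is None:
            anchors_z = ANCHOR_Z_O2 if profile.species == "O2" else ANCHOR_Z_H2O2
        c = profile.interp(anchors_z)
        return cls(profile.species, E_appl, tuple(anchors_z), tuple(float(v) for v in c))

    def to_json(self) -> dict:
        return {
            "species": self.species,
            "E_appl_V": self.E_appl,
            "anchors": [
                {"z_um": z, "c_mM": c} for z, c in zip(self.anchors_z, self.anchors_c)
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TargetProfile":
        return cls(
            species=obj["species"],
            E_appl=obj["E_appl_V"],
            anchors_z=tuple(a["z_um"] for a in obj["anchors"]),
            anchors_c=tuple(a["c_mM"] for a in obj["anchors"]),
        )

    @classmethod
    def read(cls, path) -> "TargetProfile":
        """Load a target from JSON ({species, E_appl_V, anchors}) or CSV (z_um, c_mM)."""
        path = str(path)
        if path.endswith(".json"):
            with open(path) as fh:
                return cls.from_json(json.load(fh))
        frame = pd.read_csv(path)
        if not {"species", "E_appl_V", "z_um", "c_mM"} <= set(frame.columns):
            raise ValueError("target CSV needs columns species, E_appl_V, z_um, c_mM")
        return cls(
            species=str(frame["species"].iloc[0]),
            E_appl=float(frame["E_appl_V"].iloc[0]),
            anchors_z=tuple(frame["z_um"]),
            anchors_c=tuple(frame["c_mM"]),
        )


@dataclass
class DesignResult:
    """Ranked candidate morphologies for one target."""

    candidates: pd.DataFrame  # columns rank, P_um, D_um, L_um, score
    target: TargetProfile
    n_evaluated: int
    seed: int
    metadata: dict = field(default_factory=dict)

    def top(self, k: int = 1) -> list[tuple[Morphology, float]]:
        rows = self.candidates.head(k)
        return [
            (Morphology(r.P_um, r.D_um, r.L_um), float(r.score))
            for r in rows.itertuples()
        ]


def similarity_score(predicted: GradientProfile, target: TargetProfile) -> float:
    """S = 1 - mean relative error at the target anchors (fraction; 1 = perfect)."""
    pred = predicted.interp(target.anchors_z)
    t = np.asarray(target.anchors_c)
    return float(1.0 - np.mean(np.abs(pred - t) / t))


def _interp_rows(Y: np.ndarray, z_anchor: np.ndarray) -> np.ndarray:
    """Linearly interpolate each 20-point row of Y at the anchor heights."""
    from .solver import PROFILE_Z_UM

    z = PROFILE_Z_UM
    idx = np.clip(np.searchsorted(z, z_anchor) - 1, 0, len(z) - 2)
    w = (z_anchor - z[idx]) / (z[idx + 1] - z[idx])
    w = np.clip(w, 0.0, 1.0)
    return Y[:, idx] * (1.0 - w) + Y[:, idx + 1] * w


def search_morphologies(
    model: SurrogateModel,
    target: TargetProfile,
    n_eval: int,
    seed: int = 0,
    ranges: dict | None = None,
) -> DesignResult:
    """Random search: draw, score with the surrogate, keep the best.

    Candidates are uniform over the morphology block (D >= P redrawn) at the
    target's fixed potential.  At most 10,000 are retained, ordered by score
    descending with deterministic ties (then P, D, L ascending).
    """
    if n_eval < 1:
        raise ValueError("n_eval must be >= 1")
    if model.species != target.species:
        raise ValueError(
            f"model predicts {model.species} but the target is {target.species}"
        )
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)

    def draw(m: int) -> np.ndarray:
        return np.column_stack([rng.uniform(*ranges[k], size=m) for k in ("P", "D", "L")])

    K = draw(n_eval)
    bad = K[:, 1] >= K[:, 0]
    while bad.any():
        K[bad] = draw(int(bad.sum()))
        bad = K[:, 1] >= K[:, 0]

    X = np.column_stack([np.full(n_eval, target.E_appl), K])
    pred = model.predict_batch(X, warn_out_of_range=False)
    at_anchors = _interp_rows(pred, np.asarray(target.anchors_z))
    t = np.asarray(target.anchors_c)
    scores = 1.0 - np.mean(np.abs(at_anchors - t) / t, axis=1)

    order = np.lexsort((K[:, 2], K[:, 1], K[:, 0], -scores))
    keep = order[: min(n_eval, MAX_RETAINED)]
    frame = pd.DataFrame({
        "rank": np.arange(1, len(keep) + 1),
        "P_um": K[keep, 0],
        "D_um": K[keep, 1],
        "L_um": K[keep, 2],
        "score": scores[keep],
    })
    return DesignResult(
        candidates=frame, target=target, n_evaluated=n_eval, seed=seed,
        metadata={"retained": len(keep)},
    )


def slice_score_map(
    result: DesignResult,
    L_bands: dict[float, tuple[float, float]] | None = None,
    p_bin_um: float = 2.0,
    d_bin_um: float = 0.5,
) -> dict[float, pd.DataFrame]:
    """Aggregate retained candidates into per-L-band (P, D) score maps.

    Each band's map averages the scores of its candidates on a regular
    (P, D) grid; empty bins are NaN (missing), never zero.  Returns
    ``{band_label: DataFrame}`` with D-bin centers as index and P-bin centers
    as columns.
    """
    if result.candidates.empty:
        raise ValueError("design result holds no candidates")
    L_bands = L_bands or DEFAULT_L_BANDS
    (p_lo, p_hi), (d_lo, d_hi) = DEFAULT_RANGES["P"], DEFAULT_RANGES["D"]
    p_edges = np.arange(p_lo, p_hi + p_bin_um, p_bin_um)
    d_edges = np.arange(d_lo, d_hi + d_bin_um, d_bin_um)
    c = result.candidates
    out = {}
    for label, (lo, hi) in L_bands.items():
        sel = c[(c.L_um >= lo) & (c.L_um < hi)]
        grid_sum = np.zeros((len(d_edges) - 1, len(p_edges) - 1))
        grid_n = np.zeros_like(grid_sum)
        if len(sel):
            pi = np.clip(np.digitize(sel.P_um, p_edges) - 1, 0, len(p_edges) - 2)
            di = np.clip(np.digitize(sel.D_um, d_edges) - 1, 0, len(d_edges) - 2)
            np.add.at(grid_sum, (di, pi), sel.score)
            np.add.at(grid_n, (di, pi), 1.0)
        with np.errstate(invalid="ignore"):
            grid = np.where(grid_n > 0, grid_sum / np.where(grid_n > 0, grid_n, 1), np.nan)
        out[label] = pd.DataFrame(
            grid,
            index=0.5 * (d_edges[:-1] + d_edges[1:]),
            columns=0.5 * (p_edges[:-1] + p_edges[1:]),
        )
    return out


def plot_score_maps(maps: dict[float, pd.DataFrame], path, floor: float = 0.0) -> None:
    """Render the sliced score maps as one row of heatmaps (PNG/PDF by suffix).

    Scores below ``floor`` are displayed at the floor for readability; the
    raw values live in the CSV exports.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(maps), figsize=(3.2 * len(maps), 3.2),
                             sharey=True, constrained_layout=True)
    for ax, (label, grid) in zip(np.atleast_1d(axes), sorted(maps.items())):
        shown = np.maximum(grid.to_numpy(), floor)
        im = ax.pcolormesh(grid.columns, grid.index, shown, vmin=floor, vmax=1.0,
                           cmap="RdYlBu_r")
        ax.set_title(f"L = {label:g} um")
        ax.set_xlabel("P (um)")
    np.atleast_1d(axes)[0].set_ylabel("D (um)")
    fig.colorbar(im, ax=np.atleast_1d(axes)[-1], label="similarity score")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def verify_design(
    candidate: Morphology,
    target: TargetProfile,
    catalyst: str | CatalystKinetics | None = None,
    settings: SolverSettings | None = None,
) -> tuple[GradientProfile, float, float]:
    """Re-simulate a candidate with the full solver and score it against the target.

    Returns (profile, anchor MSE in mM^2, similarity score).  The catalyst
    defaults to the species' production electrode (Pt for O2, Au for H2O2).
    """
    if catalyst is None:
        catalyst = "pt" if target.species == "O2" else "au"
    o2, h2o2 = simulate(candidate, catalyst, target.E_appl, settings)
    profile = o2 if target.species == "O2" else h2o2
    pred = profile.interp(target.anchors_z)
    t = np.asarray(target.anchors_c)
    mse = float(np.mean((pred - t) ** 2))
    return profile, mse, similarity_score(profile, target)
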