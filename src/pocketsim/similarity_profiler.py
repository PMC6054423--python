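"""All-against-all probe-pair PMScore sweeps and similarity profiles.

For two structures, each carrying a probe grid, every (probe_a, probe_b)
pair is compared at every radius of a schedule: the pattern around each
probe is re-extracted at that radius and scored.  The per-pair mean over
the schedule is the similarity profile — the quantity rendered as the
heatmaps practitioners inspect — and pairs at or above a threshold
(default 0.5) delimit the "similar zones" of the two cavities.

The same machinery scores a conformational ensemble against a reference
ligand-defined site, one mean score per frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .pocket_core import PocketSite, SiteExtractor, distance_sets, pm_score
from .probe_grid import ProbeGrid, sort_probes_by_axis
from .structure_io import LigandAtoms, Structure


@dataclass
class RadiusSchedule:
    """Ascending shell radii: start, start+step, ... up to stop.

    ``inclusive`` keeps stop when it lies on the step lattice (3→10 by
    0.5 gives 15 radii); ``half-open`` keeps strictly-below-stop values
    (3→10 by 0.1 gives 70 radii).
    """

    start: float
    stop: float
    step: float
    convention: Literal["inclusive", "half-open"]
    radii: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")
        if self.start > self.stop:
            raise ValueError("start must be <= stop")
        span = self.stop - self.start
        if self.convention == "inclusive":
            n = int(np.floor(span / self.step + 1e-9)) + 1
        elif self.convention == "half-open":
            n = max(int(np.ceil(span / self.step - 1e-9)), 1)
        else:
            raise ValueError(f"unknown convention {self.convention!r}")
        self.radii = self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return len(self.radii)

    def __iter__(self):
        return iter(self.radii)


def radius_schedule(start: float, stop: float, step: float,
                    convention: str = "inclusive") -> RadiusSchedule:
    return RadiusSchedule(start, stop, step, convention)  # type: ignore[arg-type]


#: the two schedules used throughout: a coarse 15-radius sweep for
#: probe-grid profiling and a fine 70-radius sweep for ensemble scoring
COARSE_SCHEDULE = radius_schedule(3.0, 10.0, 0.5, "inclusive")
FINE_SCHEDULE = radius_schedule(3.0, 10.0, 0.1, "half-open")


@dataclass
class SimilarityProfile:
    probe_ids_a: list[int]
    probe_ids_b: list[int]
    mean_scores: np.ndarray              # |A| × |B|
    radii: np.ndarray
    per_radius: np.ndarray | None = None  # |A| × |B| × |radii|

    @property
    def n_comparisons(self) -> int:
        return len(self.probe_ids_a) * len(self.probe_ids_b) * len(self.radii)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean_scores, index=self.probe_ids_a,
                            columns=self.probe_ids_b)


@dataclass
class SimilarZones:
    """Probe pairs at/above the similarity threshold and the probes they cover."""

    threshold: float
    similar_pairs: list[tuple[int, int, float]]
    similar_probes_a: set[int]
    similar_probes_b: set[int]


@dataclass
class EnsembleProfile:
    frame_ids: list[int]
    scores: np.ndarray          # NaN for frames flagged missing
    cutoff: float
    radii: np.ndarray
    missing: list[int] = field(default_factory=list)


def count_comparisons(n_probes_a: int, n_probes_b: int, n_radii: int) -> int:
    """Number of PMScore evaluations a profile run will enumerate.

    Pure integer bookkeeping — lets callers verify sweep sizes (e.g.
    192·192·15 = 552,960) without evaluating a single score.
    """
    return int(n_probes_a) * int(n_probes_b) * int(n_radii)


def _distance_sets_by_radius(structure: Structure, grid: ProbeGrid,
                             ordered_ids: list[int],
                             radii: np.ndarray, tag_table=None):
    """Per (probe, radius) distance sets, probes in `ordered_ids` order."""
    ex = SiteExtractor(structure, tag_table)
    pos_by_id = dict(grid.probes)
    out = []
    for pid in ordered_ids:
        probe = pos_by_id[pid]
        dmin = ex.min_distances_to(probe[None, :])
        row = []
        for r in radii:
            from .pocket_core import _site_from_mask
            site = _site_from_mask(ex.points, dmin <= r, probe, float(r))
            row.append(distance_sets(site))
        out.append(row)
    return out


def profile(struct_a: Structure, grid_a: ProbeGrid,
            struct_b: Structure, grid_b: ProbeGrid,
            radii: RadiusSchedule, tol: float = 0.5,
            sort_axis: str | None = None,
            keep_per_radius: bool = False,
            tag_table=None) -> SimilarityProfile:
    """All-against-all probe-pair PMScore sweep over a radius schedule.

    Every (probe_a, probe_b, radius) triple is scored independently;
    the result is order-independent and rows/columns are sorted along
    `sort_axis` (default: each grid's long axis).  Radii at which a
    pattern is empty contribute score 0 to the mean rather than being
    dropped — small shells legitimately catch nothing.
    """
    if len(grid_a) == 0 or len(grid_b) == 0:
        raise ValueError("probe grids must be non-empty")
    ids_a = sort_probes_by_axis(grid_a, sort_axis)
    ids_b = sort_probes_by_axis(grid_b, sort_axis)
    rr = np.asarray(radii.radii if isinstance(radii, RadiusSchedule) else radii,
                    dtype=float)

    sets_a = _distance_sets_by_radius(struct_a, grid_a, ids_a, rr, tag_table)
    sets_b = _distance_sets_by_radius(struct_b, grid_b, ids_b, rr, tag_table)

    tensor = np.zeros((len(ids_a), len(ids_b), len(rr)))
    for i, row_a in enumerate(sets_a):
        for j, row_b in enumerate(sets_b):
            for k in range(len(rr)):
                tensor[i, j, k] = pm_score(row_a[k], row_b[k], tol).score
    return SimilarityProfile(
        probe_ids_a=ids_a, probe_ids_b=ids_b,
        mean_scores=tensor.mean(axis=2), radii=rr,
        per_radius=tensor if keep_per_radius else None,
    )


def classify(prof: SimilarityProfile, threshold: float = 0.5,
             aggregate: Literal["any", "mean"] = "any") -> SimilarZones:
    """Flag probe pairs whose mean PMScore reaches the threshold.

    A pair at exactly the threshold counts ("0.5 or higher").  A probe
    joins the similar set when it appears in at least one flagged pair
    (``aggregate="any"``, default) or when its mean score over all
    partners reaches the threshold (``aggregate="mean"``).
    """
    M = prof.mean_scores
    pairs = [
        (prof.probe_ids_a[i], prof.probe_ids_b[j], float(M[i, j]))
        for i, j in zip(*np.nonzero(M >= threshold))
    ]
    if aggregate == "any":
        sa = {p for p, _, _ in pairs}
        sb = {q for _, q, _ in pairs}
    else:
        sa = {prof.probe_ids_a[i] for i in range(M.shape[0])
              if M[i].mean() >= threshold}
        sb = {prof.probe_ids_b[j] for j in range(M.shape[1])
              if M[:, j].mean() >= threshold}
    return SimilarZones(threshold=threshold, similar_pairs=pairs,
                        similar_probes_a=sa, similar_probes_b=sb)


def _frame_sets(structure: Structure, ligand: LigandAtoms, cutoff: float,
                rr: np.ndarray, tag_table=None):
    """Distance sets of the ligand site of one frame, one per radius.

    The ligand cutoff fixes the candidate residues; each radius keeps
    the candidates with an atom within that distance of the ligand
    centroid, mirroring the growing shells of the dummy-atom sweep.
    """
    from .pocket_core import _site_from_mask

    ex = SiteExtractor(structure, tag_table)
    d_lig = ex.min_distances_to(ligand.coords())
    d_cen = ex.min_distances_to(ligand.centroid()[None, :])
    candidates = d_lig <= cutoff
    out = []
    for r in rr:
        site = _site_from_mask(ex.points, candidates & (d_cen <= r),
                               ligand.centroid(), float(r))
        out.append(distance_sets(site))
    return out


def ensemble_profile(frames: Sequence[tuple[Structure, LigandAtoms | None]],
                     reference: tuple[Structure, LigandAtoms],
                     cutoff: float, radii: RadiusSchedule,
                     tol: float = 0.5, tag_table=None) -> EnsembleProfile:
    """Score every ensemble frame's ligand site against a reference site.

    Per frame, the site is the residues within `cutoff` of the ligand,
    compared with the reference site shell-by-shell over the radius
    schedule and averaged.  Frames missing the ligand are scored NaN and
    flagged; the run continues.
    """
    rr = np.asarray(radii.radii if isinstance(radii, RadiusSchedule) else radii,
                    dtype=float)
    ref_struct, ref_ligand = reference
    ref_sets = _frame_sets(ref_struct, ref_ligand, cutoff, rr, tag_table)

    scores = np.full(len(frames), np.nan)
    missing: list[int] = []
    for k, (struct, ligand) in enumerate(frames):
        if ligand is None or not ligand.atoms:
            missing.append(k)
            continue
        frame_sets = _frame_sets(struct, ligand, cutoff, rr, tag_table)
        # shells empty on BOTH sides carry no information and are
        # excluded from the mean (a self-comparison must score 1)
        per_r = [pm_score(fs, rs, tol).score
                 for fs, rs in zip(frame_sets, ref_sets)
                 if not (fs.is_empty and rs.is_empty)]
        scores[k] = float(np.mean(per_r)) if per_r else 0.0
    return EnsembleProfile(frame_ids=list(range(len(frames))), scores=scores,
                           cutoff=cutoff, radii=rr, missing=missing)


def export_profile(prof: SimilarityProfile, path: str | Path,
                   format: Literal["tsv", "json"] = "tsv") -> None:
    """Write a profile: TSV (mean-score matrix at 4 decimals, probe-id
    headers) or JSON (full contents, per-radius tensor when present)."""
    path = Path(path)
    if format == "tsv":
        prof.to_frame().to_csv(path, sep="\t", float_format="%.4f",
                               index_label="probe")
    elif format == "json":
        payload = {
            "probe_ids_a": prof.probe_ids_a,
            "probe_ids_b": prof.probe_ids_b,
            "radii": prof.radii.tolist(),
            "mean_scores": prof.mean_scores.tolist(),
            "per_radius": (prof.per_radius.tolist()
                           if prof.per_radius is not None else None),
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown format {format!r}")


def load_profile(path: str | Path) -> SimilarityProfile:
    """Read back a JSON profile written by :func:`export_profile`."""
    payload = json.loads(Path(path).read_text())
    per_radius = payload.get("per_radius")
    return SimilarityProfile(
        probe_ids_a=list(payload["probe_ids_a"]),
        probe_ids_b=list(payload["probe_ids_b"]),
        mean_scores=np.asarray(payload["mean_scores"], dtype=float),
        radii=np.asarray(payload["radii"], dtype=float),
        per_radius=None if per_radius is None else np.asarray(per_radius),
    )


def plot_profile(prof: SimilarityProfile, path: str | Path,
                 cmap: str = "coolwarm") -> None:
    """Basic heatmap of the mean-score matrix (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(prof.mean_scores, cmap=cmap, vmin=0.0, vmax=1.0,
                   origin="lower", aspect="auto")
    ax.set_xlabel("probe (structure B, axis-sorted)")
    ax.set_ylabel("probe (structure A, axis-sorted)")
    fig.colorbar(im, ax=ax, label="mean PMScore")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
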