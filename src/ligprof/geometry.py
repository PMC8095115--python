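"""Minimum-distance series, rigid superposition and ligand RMSD.

The RMSD convention follows the usual trajectory-analysis recipe: for
each frame and subunit, superpose the frame onto the initial
configuration using an alignment selection of protein atoms belonging to
that subunit (least-squares optimal proper rotation, Kabsch), then
measure the heavy-atom RMSD of the target (the bound ligand) without any
further fitting.  A ligand that co-moves rigidly with its subunit
therefore scores zero; genuine pose instability shows up directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .core import (
    DegenerateGeometryError,
    Ensemble,
    LigandSpec,
    ResidueKey,
    SelectionError,
)

__all__ = [
    "DistanceSeries",
    "RMSDSeries",
    "min_distance_series",
    "mean_separation_report",
    "superpose",
    "rmsd_series",
]


@dataclass
class DistanceSeries:
    """Per-frame, per-subunit minimum sidechain-headgroup distance (Å)."""

    residue: ResidueKey
    subunit_ids: tuple[str, ...]
    values: np.ndarray  # (T, S)

    @property
    def subunit_mean(self) -> np.ndarray:
        """Distance series averaged over the symmetry-related subunits."""
        return self.values.mean(axis=1)

    @property
    def overall_mean(self) -> float:
        return float(self.subunit_mean.mean())

    def to_frame(self) -> pd.DataFrame:
        T, S = self.values.shape
        rows = {
            "frame": np.repeat(np.arange(T), S),
            "subunit": np.tile(self.subunit_ids, T),
            "distance": self.values.reshape(-1),
        }
        df = pd.DataFrame(rows)
        df.insert(0, "residue_seq", self.residue[0])
        df.insert(1, "residue_name", self.residue[1])
        return df


@dataclass
class RMSDSeries:
    """Per-frame, per-subunit RMSD (Å) relative to frame 0."""

    target_label: str
    subunit_ids: tuple[str, ...]
    values: np.ndarray  # (T, S)
    alignment: str  # human-readable descriptor of the align_on selection

    @property
    def subunit_mean(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def time_average(self) -> float:
        """Time-averaged RMSD over frames 1..T-1 and all subunits."""
        if self.values.shape[0] < 2:
            return 0.0
        return float(self.values[1:].mean())

    def to_frame(self) -> pd.DataFrame:
        T, S = self.values.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(T), S),
                "subunit": np.tile(self.subunit_ids, T),
                "rmsd": self.values.reshape(-1),
            }
        )


def min_distance_series(
    ensemble: Ensemble,
    residues: list[ResidueKey],
    ligand: LigandSpec,
    pairing: dict[str, str] | None = None,
) -> dict[ResidueKey, DistanceSeries | str]:
    """Minimum sidechain-headgroup distance per frame and subunit.

    For each requested residue the minimum is taken over all pairs of
    that residue's sidechain heavy atoms and the heavy headgroup atoms of
    the subunit's ligand.  A residue with no sidechain heavy atoms (e.g.
    glycine) yields an error string entry instead of aborting the batch.
    """
    from .contacts import _resolve_pairing  # shared pairing logic

    topo = ensemble.topology
    pair_map = _resolve_pairing(ensemble, ligand, pairing)
    subunits = tuple(sorted(pair_map))
    T = ensemble.n_frames
    out: dict[ResidueKey, DistanceSeries | str] = {}
    hg = {
        su: ligand.headgroup_indices(topo, pair_map[su]) for su in subunits
    }
    for key in residues:
        seq, name = key
        values = np.empty((T, len(subunits)))
        bad = None
        for j, su in enumerate(subunits):
            sc = topo.select(
                subunit=su,
                residue_seq=seq,
                residue_name=name,
                category="protein_sidechain",
                heavy_only=True,
            )
            if sc.size == 0:
                bad = (
                    f"residue {name}{seq} has no sidechain heavy atoms on "
                    f"subunit {su}"
                )
                break
            # (T, n_sc, n_hg) pair distances; residue selections are small
            diff = (
                ensemble.coords[:, sc, None, :]
                - ensemble.coords[:, None, hg[su], :]
            )
            values[:, j] = np.sqrt((diff**2).sum(axis=-1)).min(axis=(1, 2))
        out[key] = bad if bad else DistanceSeries(key, subunits, values)
    return out


def mean_separation_report(
    series: dict[ResidueKey, DistanceSeries | str] | list[DistanceSeries],
    reference: ResidueKey | None = None,
    margin: float = 4.0,
) -> pd.DataFrame:
    """Table of time/subunit-averaged separations, sorted ascending.

    With a ``reference`` residue, residues whose mean separation exceeds
    the reference's by more than ``margin`` Å are flagged ``far`` — the
    screen used to discard apparent contacts that are in fact remote.
    """
    if isinstance(series, dict):
        items = [s for s in series.values() if isinstance(s, DistanceSeries)]
    else:
        items = list(series)
    if not items:
        raise SelectionError("no distance series to report")
    df = pd.DataFrame(
        {
            "residue_seq": [s.residue[0] for s in items],
            "residue_name": [s.residue[1] for s in items],
            "mean_distance": [s.overall_mean for s in items],
        }
    ).sort_values("mean_distance", ignore_index=True)
    if reference is not None:
        ref_rows = df[
            (df["residue_seq"] == reference[0])
            & (df["residue_name"] == reference[1])
        ]
        if ref_rows.empty:
            raise SelectionError(f"reference residue {reference} not in series")
        ref_mean = float(ref_rows["mean_distance"].iloc[0])
        df["far"] = df["mean_distance"] > ref_mean + margin
    return df


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.  The
    rotation is always proper (determinant +1); a reflection that would
    fit better is corrected by flipping the smallest singular axis, as
    usual for chiral molecules.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or (near-)collinear configurations, where
        the rotation is not determined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (M, 3)")
    m = mobile.shape[0]
    if m < 3:
        raise DegenerateGeometryError(
            f"superposition needs >= 3 points, got {m}"
        )
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be nonnegative with positive sum")
        w = w / w.sum()
    mob_c = (w[:, None] * mobile).sum(axis=0)
    ref_c = (w[:, None] * reference).sum(axis=0)
    mob0 = mobile - mob_c
    ref0 = reference - ref_c
    sing = np.linalg.svd(ref0 * np.sqrt(w)[:, None], compute_uv=False)
    if sing[1] <= 1e-8 * max(sing[0], 1.0):
        raise DegenerateGeometryError(
            "reference points are (near-)collinear; rotation undetermined"
        )
    rot, rssd = Rotation.align_vectors(ref0, mob0, weights=w)
    rotation = rot.as_matrix()
    translation = ref_c - rotation @ mob_c
    fitted = mobile @ rotation.T + translation
    rmsd = float(
        np.sqrt((w * ((fitted - reference) ** 2).sum(axis=1)).sum())
    )
    return rotation, translation, rmsd


def _resolve_target(
    ensemble: Ensemble,
    target: LigandSpec | list[ResidueKey],
    subunit: str,
    ligand_subunit: str,
) -> np.ndarray:
    topo = ensemble.topology
    if isinstance(target, LigandSpec):
        return target.ligand_indices(topo, ligand_subunit, heavy_only=True)
    idx_list = []
    for seq, name in target:
        idx_list.append(
            topo.select(
                subunit=subunit,
                residue_seq=seq,
                residue_name=name,
                heavy_only=True,
            )
        )
    return np.concatenate(idx_list) if idx_list else np.array([], dtype=int)


def default_alignment_selection(
    ensemble: Ensemble,
    subunit: str,
    site_indices: np.ndarray,
    radius: float = 15.0,
) -> np.ndarray:
    """Cα atoms of a subunit within ``radius`` Å of the site in frame 0.

    The "site" is usually the target's heavy atoms in the initial
    configuration; aligning on the local Cα cage keeps the measurement
    insensitive to slow global drift of the tetramer.
    """
    topo = ensemble.topology
    ca = topo.select(
        subunit=subunit, category="protein_backbone", atom_name=["CA"]
    )
    if ca.size == 0 or site_indices.size == 0:
        return ca
    ref = ensemble.coords[0]
    d = np.linalg.norm(
        ref[ca][:, None, :] - ref[site_indices][None, :, :], axis=-1
    ).min(axis=1)
    near = ca[d <= radius]
    return near if near.size >= 3 else ca


def rmsd_series(
    ensemble: Ensemble,
    target: LigandSpec | list[ResidueKey],
    align_on: dict[str, np.ndarray] | None = None,
    reference_frame: int = 0,
    pairing: dict[str, str] | None = None,
    mode: str = "per_subunit",
) -> RMSDSeries:
    """Heavy-atom RMSD of a target vs the initial configuration.

    Parameters
    ----------
    ensemble
        The trajectory ensemble.
    target
        A :class:`LigandSpec` (one bound copy per subunit) or a list of
        protein residue keys.
    align_on
        Map subunit -> atom indices used for superposition.  Defaults to
        the Cα atoms of each subunit within 15 Å of the target in the
        reference frame.
    reference_frame
        Index of the reference configuration (default 0).
    mode
        ``per_subunit`` (default) aligns each subunit independently;
        ``global`` aligns the whole complex once per frame on the union
        of the per-subunit selections.
    """
    from .contacts import _resolve_pairing

    T = ensemble.n_frames
    if not 0 <= reference_frame < T:
        raise IndexError(
            f"reference frame {reference_frame} out of range (T={T})"
        )
    if mode not in ("per_subunit", "global"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if isinstance(target, LigandSpec):
        pair_map = _resolve_pairing(ensemble, target, pairing)
        label = target.label
    else:
        topo = ensemble.topology
        prot = sorted(set(topo.subunit[topo.category == "protein_sidechain"]))
        pair_map = {s: s for s in prot}
        label = ",".join(f"{n}{s}" for s, n in target)
    subunits = tuple(sorted(pair_map))

    targets: dict[str, np.ndarray] = {}
    aligns: dict[str, np.ndarray] = {}
    for su in subunits:
        t_idx = _resolve_target(ensemble, target, su, pair_map[su])
        if t_idx.size == 0:
            raise SelectionError(f"target resolves to no heavy atoms on {su!r}")
        targets[su] = t_idx
        a_idx = (
            align_on[su]
            if align_on is not None
            else default_alignment_selection(ensemble, su, t_idx)
        )
        if a_idx.size < 3:
            raise SelectionError(
                f"alignment selection on subunit {su!r} has fewer than 3 atoms"
            )
        aligns[su] = np.asarray(a_idx, dtype=int)

    ref = ensemble.coords[reference_frame]
    values = np.empty((T, len(subunits)))
    if mode == "global":
        all_align = np.concatenate([aligns[su] for su in subunits])
    for t in range(T):
        frame = ensemble.coords[t]
        if mode == "global":
            rot, trans, _ = superpose(frame[all_align], ref[all_align])
        for j, su in enumerate(subunits):
            if mode == "per_subunit":
                rot, trans, _ = superpose(frame[aligns[su]], ref[aligns[su]])
            moved = frame[targets[su]] @ rot.T + trans
            delta = moved - ref[targets[su]]
            values[t, j] = np.sqrt((delta**2).sum(axis=1).mean())
    descriptor = (
        "user-supplied" if align_on is not None else "CA within 15 A of target"
    ) + f" ({mode})"
    return RMSDSeries(label, subunits, values, descriptor)
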