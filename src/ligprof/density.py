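"""Frame-averaged atomic density maps, map correlation, water bridges.

A density map deposits, for every selected heavy atom in every frame, an
isotropic Gaussian kernel of standard deviation ``atom_size`` truncated
at 4σ on a regular grid of spacing ``resolution``.  Each kernel is
normalised so that its discrete sum times the voxel volume equals the
atom's weight (its mass, or 1 in occupancy mode); per-frame maps are
combined by arithmetic averaging.  "Resolution" is therefore the grid
spacing and "atom size" the kernel σ — both configurable, since grid
tools differ on kernel semantics.

Map-map agreement is quantified as the Pearson correlation over the
spatially overlapping voxels after trilinear resampling of the second
map onto the first map's grid.

The water-bridge analysis counts frames in which some water oxygen sits
simultaneously within a donor-acceptor distance (default 3.5 Å) of a
polar (N/O) sidechain heavy atom of a residue and a polar heavy atom of
the ligand.  No angular criterion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .core import (
    ConfigurationError,
    DensityMap,
    Ensemble,
    LigandSpec,
    ResidueKey,
    SelectionError,
)

__all__ = [
    "MapComparison",
    "BridgeReport",
    "atomic_density_map",
    "map_correlation",
    "water_occupancy_map",
    "water_bridge_frequency",
]

#: Kernel truncation radius in units of sigma.
TRUNCATION_SIGMAS = 4.0

POLAR_ELEMENTS = ("N", "O")


@dataclass
class MapComparison:
    """Agreement between two density maps on a common grid.

    ``correlation`` is the correlation about zero (normalised overlap,
    the default convention of volume-comparison tools), which for two
    unit Gaussian kernels of width σ offset by δ equals
    ``exp(-δ²/(4σ²))``.  ``correlation_about_mean`` is the conventional
    Pearson coefficient over the masked voxels; it can be negative.
    """

    correlation: float
    correlation_about_mean: float
    n_voxels_compared: int
    mask_threshold: float
    resampling: str = "trilinear"

    def __post_init__(self) -> None:
        if self.n_voxels_compared <= 0:
            raise ValueError("n_voxels_compared must be positive")
        for value in (self.correlation, self.correlation_about_mean):
            if not -1.0 - 1e-9 <= value <= 1.0 + 1e-9:
                raise ValueError("correlation out of [-1, 1]")
        self.correlation = float(np.clip(self.correlation, -1.0, 1.0))
        self.correlation_about_mean = float(
            np.clip(self.correlation_about_mean, -1.0, 1.0)
        )


@dataclass
class BridgeReport:
    """Occupancy of a water-mediated residue-ligand bridge."""

    residue: ResidueKey
    ligand_label: str
    d_bridge: float
    subunit_ids: tuple[str, ...]
    indicators: np.ndarray  # (T, S) boolean

    @property
    def per_subunit_frequency(self) -> np.ndarray:
        return self.indicators.mean(axis=0)

    @property
    def bridge_frequency(self) -> float:
        return float(self.indicators.mean())

    def to_frame(self) -> pd.DataFrame:
        T, S = self.indicators.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(T), S),
                "subunit": np.tile(self.subunit_ids, T),
                "bridged": self.indicators.reshape(-1).astype(int),
            }
        )


def _grid_geometry(
    points: np.ndarray, spacing: float, pad: float
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Origin (snapped to a spacing multiple) and dims covering points."""
    lo = points.reshape(-1, 3).min(axis=0) - pad
    hi = points.reshape(-1, 3).max(axis=0) + pad
    origin = np.floor(lo / spacing) * spacing
    dims = tuple(int(np.ceil((hi[d] - origin[d]) / spacing)) + 1 for d in range(3))
    return origin, dims


def _deposit_frame(
    grid: np.ndarray,
    origin: np.ndarray,
    spacing: float,
    positions: np.ndarray,
    weights: np.ndarray,
    sigma: float,
) -> None:
    """Add truncated, per-atom-normalised Gaussian kernels to ``grid``."""
    half = int(np.ceil(TRUNCATION_SIGMAS * sigma / spacing))
    voxel_volume = spacing**3
    dims = grid.shape
    for pos, w in zip(positions, weights):
        centre = (pos - origin) / spacing
        c = np.round(centre).astype(int)
        axes_g = []
        slices = []
        for d in range(3):
            lo = max(c[d] - half, 0)
            hi = min(c[d] + half, dims[d] - 1)
            if lo > hi:
                break
            idx = np.arange(lo, hi + 1)
            x = (idx - centre[d]) * spacing
            axes_g.append(np.exp(-0.5 * (x / sigma) ** 2))
            slices.append(slice(lo, hi + 1))
        else:
            kernel = np.einsum("i,j,k->ijk", *axes_g)
            total = kernel.sum()
            if total > 0:
                grid[slices[0], slices[1], slices[2]] += (
                    kernel * (w / (total * voxel_volume))
                )


def atomic_density_map(
    ensemble: Ensemble,
    selection: np.ndarray,
    resolution: float = 0.5,
    atom_size: float = 1.0,
    weight_mode: str = "mass",
    frames: np.ndarray | None = None,
) -> DensityMap:
    """Frame-averaged weighted atomic density of a selection.

    Parameters
    ----------
    ensemble
        The trajectory ensemble.
    selection
        Atom indices to deposit (hydrogens are dropped automatically).
    resolution
        Grid spacing in Å.
    atom_size
        Gaussian kernel σ in Å.
    weight_mode
        ``mass`` deposits atomic masses (map integral = total selected
        mass per frame); ``occupancy`` deposits weight 1 per atom.
    frames
        Optional subset of frame indices; defaults to all frames.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if atom_size <= 0:
        raise ValueError(f"atom_size must be positive, got {atom_size}")
    selection = np.asarray(selection, dtype=int)
    selection = selection[~ensemble.topology.is_hydrogen[selection]]
    if selection.size == 0:
        raise SelectionError("density selection resolves to no heavy atoms")
    frame_idx = (
        np.arange(ensemble.n_frames) if frames is None else np.asarray(frames)
    )
    # grid extent always covers the selection over ALL frames, so maps of
    # frame subsets share one grid and frame averaging is exactly linear
    pts = ensemble.coords[:, selection]
    origin, dims = _grid_geometry(
        pts, resolution, pad=TRUNCATION_SIGMAS * atom_size
    )
    if weight_mode == "mass":
        weights = ensemble.topology.mass[selection]
    elif weight_mode == "occupancy":
        weights = np.ones(selection.size)
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    grid = np.zeros(dims)
    for t in frame_idx:
        _deposit_frame(
            grid, origin, resolution,
            ensemble.coords[t, selection], weights, atom_size,
        )
    grid /= len(frame_idx)
    return DensityMap(
        origin=origin,
        spacing=resolution,
        values=grid,
        weight_mode=weight_mode,
        n_frames_averaged=len(frame_idx),
    )


def map_correlation(
    map_a: DensityMap,
    map_b: DensityMap,
    mask_threshold: float = 0.0,
) -> MapComparison:
    """Correlation of two maps after resampling B onto A's grid.

    B is evaluated at A's voxel centres by trilinear interpolation (zero
    outside B's extent).  The primary ``correlation`` is computed about
    zero: ``∫AB / sqrt(∫A² ∫B²)``, with ``∫B²`` taken on B's native grid
    so that density of B falling outside A's grid still counts in the
    normalisation.  The about-mean Pearson coefficient is computed over
    the voxels where ``max(A, B) > mask_threshold`` (the empty far field
    would otherwise inflate it).
    """
    ax = map_a.axes()
    # fractional indices of A's voxel centres in B's grid
    frac = [
        (ax[d] - map_b.origin[d]) / map_b.spacing for d in range(3)
    ]
    fi, fj, fk = np.meshgrid(*frac, indexing="ij")
    inside = np.ones(fi.shape, dtype=bool)
    for f, dim in zip((fi, fj, fk), map_b.dims):
        inside &= (f >= 0) & (f <= dim - 1)
    if not inside.any():
        raise ConfigurationError("no overlapping voxels between the maps")
    coords = np.vstack([fi.ravel(), fj.ravel(), fk.ravel()])
    b_vals = map_coordinates(
        map_b.values, coords, order=1, mode="constant", cval=0.0
    ).reshape(map_a.dims)
    a_vals = map_a.values

    overlap = float((a_vals * b_vals).sum() * map_a.voxel_volume)
    norm_a = float((a_vals**2).sum() * map_a.voxel_volume)
    norm_b = float((map_b.values**2).sum() * map_b.voxel_volume)
    if norm_a == 0 or norm_b == 0:
        raise ConfigurationError("cannot correlate an all-zero map")
    corr_zero = overlap / np.sqrt(norm_a * norm_b)

    mask = np.maximum(a_vals, b_vals) > mask_threshold
    n_masked = int(mask.sum())
    if n_masked < 2:
        raise ConfigurationError(
            "fewer than 2 voxels above the mask threshold"
        )
    a_sel, b_sel = a_vals[mask], b_vals[mask]
    if np.std(a_sel) == 0 or np.std(b_sel) == 0:
        raise ConfigurationError("constant map over the compared voxels")
    corr_mean = float(np.corrcoef(a_sel, b_sel)[0, 1])
    return MapComparison(
        correlation=corr_zero,
        correlation_about_mean=corr_mean,
        n_voxels_compared=n_masked,
        mask_threshold=mask_threshold,
    )


def _anchor_indices(
    ensemble: Ensemble,
    residue: ResidueKey,
    ligand: LigandSpec,
    subunit: str,
    ligand_subunit: str,
    polar_only: bool,
    sidechain_only: bool,
) -> tuple[np.ndarray, np.ndarray]:
    topo = ensemble.topology
    seq, name = residue
    res_idx = topo.select(
        subunit=subunit,
        residue_seq=seq,
        residue_name=name,
        category=(
            ("protein_sidechain",)
            if sidechain_only
            else ("protein_sidechain", "protein_backbone")
        ),
        element=POLAR_ELEMENTS if polar_only else None,
        heavy_only=True,
    )
    lig_idx = ligand.ligand_indices(topo, ligand_subunit, heavy_only=True)
    if polar_only:
        lig_idx = lig_idx[np.isin(topo.element[lig_idx], POLAR_ELEMENTS)]
    return res_idx, lig_idx


def _water_oxygens(ensemble: Ensemble) -> np.ndarray:
    topo = ensemble.topology
    idx = topo.select(category="water", element=["O"])
    if idx.size == 0:
        raise SelectionError("no water oxygens in the topology")
    return idx


def water_occupancy_map(
    ensemble: Ensemble,
    residue: ResidueKey,
    ligand: LigandSpec,
    cutoff: float = 6.0,
    resolution: float = 0.5,
    atom_size: float = 1.0,
    pairing: dict[str, str] | None = None,
) -> DensityMap:
    """Occupancy map of waters near both a residue and the ligand.

    Per frame, every water oxygen within ``cutoff`` of a heavy atom of
    the residue (on any subunit) *and* within ``cutoff`` of a heavy atom
    of that subunit's ligand is deposited with weight 1; frames are then
    averaged, so the map integral estimates the mean number of
    simultaneously-near waters per frame.
    """
    from .contacts import _resolve_pairing

    waters = _water_oxygens(ensemble)
    pair_map = _resolve_pairing(ensemble, ligand, pairing)
    subunits = tuple(sorted(pair_map))
    anchors = {
        su: _anchor_indices(
            ensemble, residue, ligand, su, pair_map[su],
            polar_only=False, sidechain_only=False,
        )
        for su in subunits
    }
    for su, (res_idx, lig_idx) in anchors.items():
        if res_idx.size == 0:
            raise SelectionError(
                f"residue {residue} has no heavy atoms on subunit {su!r}"
            )
        if lig_idx.size == 0:
            raise SelectionError(
                f"ligand {ligand.label!r} has no heavy atoms on subunit "
                f"{pair_map[su]!r}"
            )
    T = ensemble.n_frames
    # grid over the anchor neighbourhood, fixed across frames
    anchor_idx = np.unique(
        np.concatenate([np.concatenate(v) for v in anchors.values()])
    )
    origin, dims = _grid_geometry(
        ensemble.coords[:, anchor_idx],
        resolution,
        pad=cutoff + TRUNCATION_SIGMAS * atom_size,
    )
    grid = np.zeros(dims)
    for t in range(T):
        frame = ensemble.coords[t]
        qualifying: list[np.ndarray] = []
        wpos = frame[waters]
        for su in subunits:
            res_idx, lig_idx = anchors[su]
            d_res = np.linalg.norm(
                wpos[:, None, :] - frame[res_idx][None, :, :], axis=-1
            ).min(axis=1)
            d_lig = np.linalg.norm(
                wpos[:, None, :] - frame[lig_idx][None, :, :], axis=-1
            ).min(axis=1)
            qualifying.append(waters[(d_res <= cutoff) & (d_lig <= cutoff)])
        sel = np.unique(np.concatenate(qualifying))
        if sel.size:
            _deposit_frame(
                grid, origin, resolution, frame[sel],
                np.ones(sel.size), atom_size,
            )
    grid /= T
    return DensityMap(
        origin=origin,
        spacing=resolution,
        values=grid,
        weight_mode="occupancy",
        n_frames_averaged=T,
    )


def water_bridge_frequency(
    ensemble: Ensemble,
    residue: ResidueKey,
    ligand: LigandSpec,
    d_bridge: float = 3.5,
    pairing: dict[str, str] | None = None,
) -> BridgeReport:
    """Fraction of frames with a water bridging residue and ligand.

    A frame (per subunit) counts as bridged iff some water oxygen is
    simultaneously within ``d_bridge`` of a polar (N/O) sidechain heavy
    atom of the residue and within ``d_bridge`` of a polar (N/O) heavy
    atom of the ligand.
    """
    from .contacts import _resolve_pairing

    waters = _water_oxygens(ensemble)
    pair_map = _resolve_pairing(ensemble, ligand, pairing)
    subunits = tuple(sorted(pair_map))
    anchors = {}
    for su in subunits:
        res_idx, lig_idx = _anchor_indices(
            ensemble, residue, ligand, su, pair_map[su],
            polar_only=True, sidechain_only=True,
        )
        if res_idx.size == 0:
            raise SelectionError(
                f"residue {residue[1]}{residue[0]} has no polar (N/O) "
                f"sidechain heavy atoms on subunit {su!r}"
            )
        if lig_idx.size == 0:
            raise SelectionError(
                f"ligand {ligand.label!r} has no polar (N/O) heavy atoms on "
                f"subunit {pair_map[su]!r}"
            )
        anchors[su] = (res_idx, lig_idx)
    T = ensemble.n_frames
    indicators = np.zeros((T, len(subunits)), dtype=bool)
    for t in range(T):
        frame = ensemble.coords[t]
        wpos = frame[waters]
        for j, su in enumerate(subunits):
            res_idx, lig_idx = anchors[su]
            d_res = np.linalg.norm(
                wpos[:, None, :] - frame[res_idx][None, :, :], axis=-1
            ).min(axis=1)
            d_lig = np.linalg.norm(
                wpos[:, None, :] - frame[lig_idx][None, :, :], axis=-1
            ).min(axis=1)
            indicators[t, j] = bool(
                ((d_res <= d_bridge) & (d_lig <= d_bridge)).any()
            )
    return BridgeReport(
        residue=residue,
        ligand_label=ligand.label,
        d_bridge=d_bridge,
        subunit_ids=subunits,
        indicators=indicators,
    )
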