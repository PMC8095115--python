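"""Per-residue contact fingerprints and two-ligand selectivity.

A protein residue is "in contact" with a ligand in a given frame if the
minimum distance between any of its sidechain heavy atoms and any heavy
headgroup atom of that subunit's ligand is at or below the cutoff
(default 5 Å, closed boundary).  Contact frequencies are computed per
subunit and combined across the symmetry-related subunits, by default as
the arithmetic mean of per-subunit frequencies.

Backbone atoms never count: the fingerprint is a sidechain fingerprint,
so glycine (no sidechain heavy atoms) can never register a contact.
Hydrogens are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import (
    ConfigurationError,
    Ensemble,
    LigandSpec,
    ResidueKey,
    SelectionError,
)

__all__ = [
    "ContactProfile",
    "SelectivityReport",
    "contact_frequencies",
    "classify_selectivity",
    "dual_ligand_shared_contacts",
    "write_contact_profile_tsv",
    "read_contact_profile_tsv",
]

COMBINE_MODES = ("subunit_mean", "frame_pooled")


@dataclass
class ContactProfile:
    """Contact frequencies of protein residues against one ligand.

    ``per_subunit`` maps ``(residue_key, subunit_id)`` to the fraction of
    frames in contact; ``combined`` maps ``residue_key`` to the
    subunit-combined frequency.  Residues that never make contact are
    omitted from the maps but :meth:`frequency` reports 0 for them.
    """

    ligand_label: str
    cutoff: float
    n_frames: int
    combine_mode: str
    subunit_ids: tuple[str, ...]
    per_subunit: dict[tuple[ResidueKey, str], float] = field(default_factory=dict)
    combined: dict[ResidueKey, float] = field(default_factory=dict)

    def frequency(
        self, residue: ResidueKey, subunit: str | None = None
    ) -> float:
        if subunit is None:
            return self.combined.get(residue, 0.0)
        return self.per_subunit.get((residue, subunit), 0.0)

    @property
    def residues(self) -> list[ResidueKey]:
        return sorted(self.combined)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (residue, subunit) plus combined."""
        rows = []
        for key in self.residues:
            for su in self.subunit_ids:
                rows.append(
                    {
                        "residue_seq": key[0],
                        "residue_name": key[1],
                        "subunit": su,
                        "frequency": self.frequency(key, su),
                        "combined": self.combined[key],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "residue_seq",
                "residue_name",
                "subunit",
                "frequency",
                "combined",
            ],
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        ligand_label: str,
        cutoff: float,
        n_frames: int = 0,
        combine_mode: str = "subunit_mean",
    ) -> "ContactProfile":
        subunits = tuple(sorted(df["subunit"].astype(str).unique()))
        prof = cls(ligand_label, cutoff, n_frames, combine_mode, subunits)
        for _, row in df.iterrows():
            key = (int(row["residue_seq"]), str(row["residue_name"]))
            prof.per_subunit[(key, str(row["subunit"]))] = float(
                row["frequency"]
            )
            prof.combined[key] = float(row["combined"])
        return prof


@dataclass
class SelectivityReport:
    """Partition of residues by which ligand(s) they contact persistently.

    A residue is *selective* for ligand A when its combined frequency is
    at or above the threshold for A but below it for B.  ``cumulative``
    sums the two frequencies (maximum 2), matching stacked-bar-chart
    bookkeeping of dual fingerprints.
    """

    threshold: float
    label_a: str
    label_b: str
    selective_a: list[ResidueKey]
    selective_b: list[ResidueKey]
    shared: list[ResidueKey]
    neither: list[ResidueKey]
    cumulative: dict[ResidueKey, float]

    def to_frame(self) -> pd.DataFrame:
        classes = (
            [(r, f"selective_{self.label_a}") for r in self.selective_a]
            + [(r, f"selective_{self.label_b}") for r in self.selective_b]
            + [(r, "shared") for r in self.shared]
            + [(r, "neither") for r in self.neither]
        )
        rows = [
            {
                "residue_seq": r[0],
                "residue_name": r[1],
                "class": cls_,
                "cumulative": self.cumulative[r],
            }
            for r, cls_ in sorted(classes)
        ]
        return pd.DataFrame(
            rows,
            columns=["residue_seq", "residue_name", "class", "cumulative"],
        )


def write_contact_profile_tsv(profile: ContactProfile, path) -> None:
    """Write a profile as TSV with a commented metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# ligand_label={profile.ligand_label}\n")
        fh.write(f"# cutoff={profile.cutoff}\n")
        fh.write(f"# n_frames={profile.n_frames}\n")
        fh.write(f"# combine_mode={profile.combine_mode}\n")
        profile.to_frame().to_csv(fh, sep="\t", index=False)


def read_contact_profile_tsv(path) -> ContactProfile:
    """Read a profile written by :func:`write_contact_profile_tsv`."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    return ContactProfile.from_frame(
        df,
        ligand_label=meta.get("ligand_label", "?"),
        cutoff=float(meta.get("cutoff", "nan")),
        n_frames=int(meta.get("n_frames", "0")),
        combine_mode=meta.get("combine_mode", "subunit_mean"),
    )


def _resolve_pairing(
    ensemble: Ensemble, ligand: LigandSpec, pairing: dict[str, str] | None
) -> dict[str, str]:
    """Map protein subunit -> ligand subunit (same-chain by default).

    Inter-subunit binding sites (a ligand wedged between two chains) need
    an explicit pairing map.
    """
    topo = ensemble.topology
    protein_subunits = sorted(
        set(topo.subunit[topo.category == "protein_sidechain"])
    )
    if pairing is not None:
        unknown = set(pairing.values()) - set(ligand.subunits)
        if unknown:
            raise ConfigurationError(
                f"pairing refers to ligand subunits {sorted(unknown)} that "
                f"the ligand {ligand.label!r} does not occupy"
            )
        return dict(pairing)
    ligand_subunits = set(ligand.subunits)
    missing = [s for s in protein_subunits if s not in ligand_subunits]
    if missing:
        raise ConfigurationError(
            f"no ligand {ligand.label!r} on protein subunit(s) {missing}; "
            "supply an explicit subunit-pairing map"
        )
    return {s: s for s in protein_subunits}


def _sidechain_groups(
    ensemble: Ensemble, subunit: str
) -> tuple[np.ndarray, list[ResidueKey], np.ndarray]:
    """Sidechain heavy atoms of a subunit, grouped by residue.

    Returns (atom indices, residue keys, group index per atom).
    """
    topo = ensemble.topology
    idx = topo.select(
        subunit=subunit, category="protein_sidechain", heavy_only=True
    )
    keys = sorted(
        {
            (int(s), str(n))
            for s, n in zip(topo.residue_seq[idx], topo.residue_name[idx])
        }
    )
    key_pos = {k: i for i, k in enumerate(keys)}
    groups = np.array(
        [
            key_pos[(int(s), str(n))]
            for s, n in zip(topo.residue_seq[idx], topo.residue_name[idx])
        ],
        dtype=int,
    )
    return idx, keys, groups


def contact_frequencies(
    ensemble: Ensemble,
    ligand: LigandSpec,
    cutoff: float = 5.0,
    combine_mode: str = "subunit_mean",
    pairing: dict[str, str] | None = None,
) -> ContactProfile:
    """Per-residue contact frequencies of sidechains against a headgroup.

    Parameters
    ----------
    ensemble
        Structural ensemble; all frames contribute.
    ligand
        Ligand definition naming the headgroup atoms.
    cutoff
        Contact distance in Å (closed boundary: a pair at exactly the
        cutoff counts).
    combine_mode
        ``subunit_mean`` averages per-subunit frequencies; ``frame_pooled``
        pools all subunit-frames before dividing.  The two coincide when
        every subunit contributes every frame, as here.
    pairing
        Optional explicit protein-subunit -> ligand-subunit map.
    """
    if combine_mode not in COMBINE_MODES:
        raise ConfigurationError(f"unknown combine_mode {combine_mode!r}")
    ligand.validate(ensemble.topology)
    pair_map = _resolve_pairing(ensemble, ligand, pairing)
    T = ensemble.n_frames
    subunits = tuple(sorted(pair_map))

    per_subunit_counts: dict[tuple[ResidueKey, str], int] = {}
    all_keys: set[ResidueKey] = set()
    for su in subunits:
        sc_idx, keys, groups = _sidechain_groups(ensemble, su)
        if sc_idx.size == 0:
            raise SelectionError(
                f"subunit {su!r} has no sidechain heavy atoms"
            )
        all_keys.update(keys)
        hg_idx = ligand.headgroup_indices(ensemble.topology, pair_map[su])
        if hg_idx.size == 0:
            raise SelectionError(
                f"ligand {ligand.label!r} has no heavy headgroup atoms on "
                f"subunit {pair_map[su]!r}"
            )
        counts = np.zeros(len(keys), dtype=int)
        for t in range(T):
            tree = cKDTree(ensemble.coords[t, hg_idx])
            neighbours = tree.query_ball_point(
                ensemble.coords[t, sc_idx], r=cutoff
            )
            touched = np.fromiter(
                (len(nb) > 0 for nb in neighbours), dtype=bool, count=len(sc_idx)
            )
            hit_groups = np.unique(groups[touched])
            counts[hit_groups] += 1
        for key, c in zip(keys, counts):
            if c > 0:
                per_subunit_counts[(key, su)] = int(c)

    profile = ContactProfile(
        ligand_label=ligand.label,
        cutoff=cutoff,
        n_frames=T,
        combine_mode=combine_mode,
        subunit_ids=subunits,
    )
    for (key, su), c in per_subunit_counts.items():
        profile.per_subunit[(key, su)] = c / T
    # subunit_mean and frame_pooled agree for complete per-subunit data:
    # mean_s(c_s / T) == sum_s(c_s) / (S * T)
    for key in all_keys:
        total = sum(
            per_subunit_counts.get((key, su), 0) for su in subunits
        )
        if total > 0:
            profile.combined[key] = total / (len(subunits) * T)
    return profile


def _check_compatible(a: ContactProfile, b: ContactProfile) -> None:
    if a.cutoff != b.cutoff:
        raise ConfigurationError(
            f"profiles use different cutoffs ({a.cutoff} vs {b.cutoff})"
        )
    if a.combine_mode != b.combine_mode:
        raise ConfigurationError(
            f"profiles use different combine modes "
            f"({a.combine_mode} vs {b.combine_mode})"
        )


def classify_selectivity(
    profile_a: ContactProfile,
    profile_b: ContactProfile,
    threshold: float = 0.5,
) -> SelectivityReport:
    """Partition residues into selective-A / selective-B / shared / neither.

    The threshold (default 0.5, i.e. contact in at least half of the
    frames) is applied to the subunit-combined frequencies of each
    profile; the four classes partition the union of residues seen in
    either profile.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(
            f"threshold must be in (0, 1), got {threshold}"
        )
    _check_compatible(profile_a, profile_b)
    residues = sorted(set(profile_a.combined) | set(profile_b.combined))
    report = SelectivityReport(
        threshold=threshold,
        label_a=profile_a.ligand_label,
        label_b=profile_b.ligand_label,
        selective_a=[],
        selective_b=[],
        shared=[],
        neither=[],
        cumulative={},
    )
    for r in residues:
        fa = profile_a.frequency(r)
        fb = profile_b.frequency(r)
        report.cumulative[r] = fa + fb
        if fa >= threshold and fb >= threshold:
            report.shared.append(r)
        elif fa >= threshold:
            report.selective_a.append(r)
        elif fb >= threshold:
            report.selective_b.append(r)
        else:
            report.neither.append(r)
    return report


def dual_ligand_shared_contacts(
    profile_a: ContactProfile,
    profile_b: ContactProfile,
    threshold: float = 0.5,
) -> list[ResidueKey]:
    """Residues persistently contacting both ligands.

    Convenience view over :func:`classify_selectivity`; requires the
    subunit-mean combination so the threshold means "at least this
    fraction of frames, averaged over subunits".
    """
    if profile_a.combine_mode != "subunit_mean":
        raise ConfigurationError(
            "dual_ligand_shared_contacts requires subunit_mean profiles"
        )
    return classify_selectivity(profile_a, profile_b, threshold).shared
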