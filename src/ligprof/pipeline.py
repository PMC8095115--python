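"""End-to-end analysis pipeline driven by a single YAML config.

The pipeline runs, per condition (one ensemble with one bound ligand
species): contact fingerprinting, minimum-distance series for the
persistent contacts, per-subunit ligand RMSD, a mass-weighted ligand
density map, optional correlation against a reference map, and — where a
bridge residue is named — the water-bridge report.  Conditions can then
be compared pairwise for selectivity.  Every threshold in play is echoed
into ``summary.txt`` so the report bundle is self-describing, and all
outputs are a pure function of (config, input files, seed).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contacts import (
    classify_selectivity,
    contact_frequencies,
    write_contact_profile_tsv,
)
from .core import ClassifyRules, ConfigurationError, ResidueKey
from .density import (
    atomic_density_map,
    map_correlation,
    water_bridge_frequency,
)
from .geometry import min_distance_series, rmsd_series
from .io import (
    read_density_map,
    read_ligand_spec,
    read_structure_ensemble,
    write_density_map,
)

__all__ = ["PipelineConfig", "ConditionConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("ligprof.pipeline")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names stage and input."""


@dataclass
class ConditionConfig:
    """One ensemble/ligand condition (e.g. species A at site 1)."""

    label: str
    ensemble: Path
    ligand: Path
    dialect: str = "pdb_multimodel"
    ligand_resnames: tuple[str, ...] = ()
    bridge_residue: ResidueKey | None = None
    reference_map: Path | None = None


@dataclass
class PipelineConfig:
    """Validated study configuration.

    Thresholds default to the conventional values: 5 Å contact cutoff,
    0.5 selectivity threshold, 6 Å water shell, 3.5 Å bridge distance,
    0.5 Å map resolution, 1.0 Å atom size.
    """

    conditions: list[ConditionConfig]
    output_dir: Path
    seed: int = 0
    selectivity_pairs: list[tuple[str, str]] = field(default_factory=list)
    contact_cutoff: float = 5.0
    selectivity_threshold: float = 0.5
    water_cutoff: float = 6.0
    bridge_distance: float = 3.5
    resolution: float = 0.5
    atom_size: float = 1.0
    rmsd_mode: str = "per_subunit"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent
        thresholds = raw.get("thresholds", {})
        conditions = []
        for entry in raw.get("conditions", []):
            bridge = entry.get("bridge_residue")
            ref = entry.get("reference_map")
            conditions.append(
                ConditionConfig(
                    label=str(entry["label"]),
                    ensemble=base / entry["ensemble"],
                    ligand=base / entry["ligand"],
                    dialect=entry.get("dialect", "pdb_multimodel"),
                    ligand_resnames=tuple(entry.get("ligand_resnames", [])),
                    bridge_residue=(
                        (int(bridge[0]), str(bridge[1])) if bridge else None
                    ),
                    reference_map=(base / ref) if ref else None,
                )
            )
        if not conditions:
            raise ConfigurationError(f"{path}: no conditions defined")
        config = cls(
            conditions=conditions,
            output_dir=base / raw.get("output_dir", "profiler_out"),
            seed=int(raw.get("seed", 0)),
            selectivity_pairs=[
                (str(a), str(b))
                for a, b in raw.get("selectivity_pairs", [])
            ],
            contact_cutoff=float(thresholds.get("contact_cutoff", 5.0)),
            selectivity_threshold=float(
                thresholds.get("selectivity_threshold", 0.5)
            ),
            water_cutoff=float(thresholds.get("water_cutoff", 6.0)),
            bridge_distance=float(thresholds.get("bridge_distance", 3.5)),
            resolution=float(thresholds.get("resolution", 0.5)),
            atom_size=float(thresholds.get("atom_size", 1.0)),
            rmsd_mode=str(raw.get("rmsd_mode", "per_subunit")),
        )
        config.validate()
        return config

    def validate(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("condition labels must be unique")
        for cond in self.conditions:
            for p in (cond.ensemble, cond.ligand, cond.reference_map):
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(
                        f"condition {cond.label!r}: missing input file {p}"
                    )
        for a, b in self.selectivity_pairs:
            for lab in (a, b):
                if lab not in labels:
                    raise ConfigurationError(
                        f"selectivity pair refers to unknown condition {lab!r}"
                    )


def _stage(name: str, label: str, func, timings: list[tuple[str, float]]):
    start = time.perf_counter()
    try:
        result = func()
    except Exception as exc:
        raise PipelineError(
            f"stage {name!r} failed for condition {label!r}: {exc}"
        ) from exc
    elapsed = time.perf_counter() - start
    timings.append((f"{label}/{name}", elapsed))
    logger.info("%s/%s finished in %.2f s", label, name, elapsed)
    return result


def run_pipeline(config: PipelineConfig) -> dict[str, dict[str, Path]]:
    """Run every stage; returns a map condition -> artefact name -> path.

    Any stage error aborts the run with a :class:`PipelineError` naming
    the stage and the offending condition.  TSV and DX outputs are
    byte-reproducible for identical (config, inputs, seed).
    """
    config.validate()
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    timings: list[tuple[str, float]] = []
    artefacts: dict[str, dict[str, Path]] = {}
    profiles = {}

    for cond in config.conditions:
        cond_dir = out_root / cond.label
        cond_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        rules = ClassifyRules(
            ligand_resnames=frozenset(cond.ligand_resnames) or frozenset()
        )
        ensemble = _stage(
            "read",
            cond.label,
            lambda: read_structure_ensemble(
                cond.ensemble, dialect=cond.dialect, classify_rules=rules
            ),
            timings,
        )
        ligand = read_ligand_spec(cond.ligand)

        profile = _stage(
            "contacts",
            cond.label,
            lambda: contact_frequencies(
                ensemble, ligand, cutoff=config.contact_cutoff
            ),
            timings,
        )
        profiles[cond.label] = profile
        paths["contacts"] = cond_dir / "contacts.tsv"
        write_contact_profile_tsv(profile, paths["contacts"])

        persistent = [
            r
            for r in profile.residues
            if profile.frequency(r) >= config.selectivity_threshold
        ]
        if persistent:
            series = _stage(
                "mindist",
                cond.label,
                lambda: min_distance_series(ensemble, persistent, ligand),
                timings,
            )
            frames = [
                s.to_frame()
                for s in series.values()
                if not isinstance(s, str)
            ]
            paths["mindist"] = cond_dir / "mindist.tsv"
            pd.concat(frames, ignore_index=True).to_csv(
                paths["mindist"], sep="\t", index=False, float_format="%.4f"
            )

        rmsd = _stage(
            "rmsd",
            cond.label,
            lambda: rmsd_series(ensemble, ligand, mode=config.rmsd_mode),
            timings,
        )
        paths["rmsd"] = cond_dir / "rmsd.tsv"
        rmsd.to_frame().to_csv(
            paths["rmsd"], sep="\t", index=False, float_format="%.4f"
        )

        lig_idx = np.concatenate(
            [
                ligand.ligand_indices(ensemble.topology, su)
                for su in ligand.subunits
            ]
        )
        dmap = _stage(
            "density",
            cond.label,
            lambda: atomic_density_map(
                ensemble,
                lig_idx,
                resolution=config.resolution,
                atom_size=config.atom_size,
            ),
            timings,
        )
        paths["density"] = cond_dir / "ligand_density.dx"
        write_density_map(dmap, paths["density"])

        if cond.reference_map is not None:
            reference = read_density_map(cond.reference_map)
            comparison = _stage(
                "overlap",
                cond.label,
                lambda: map_correlation(dmap, reference),
                timings,
            )
            paths["overlap"] = cond_dir / "map_overlap.tsv"
            pd.DataFrame(
                [
                    {
                        "condition": cond.label,
                        "correlation": comparison.correlation,
                        "correlation_about_mean": (
                            comparison.correlation_about_mean
                        ),
                        "n_voxels": comparison.n_voxels_compared,
                        "mask_threshold": comparison.mask_threshold,
                    }
                ]
            ).to_csv(
                paths["overlap"], sep="\t", index=False, float_format="%.6f"
            )

        if cond.bridge_residue is not None:
            bridge = _stage(
                "waterbridge",
                cond.label,
                lambda: water_bridge_frequency(
                    ensemble,
                    cond.bridge_residue,
                    ligand,
                    d_bridge=config.bridge_distance,
                ),
                timings,
            )
            paths["waterbridge"] = cond_dir / "waterbridge.tsv"
            summary = pd.DataFrame(
                [
                    {
                        "residue_seq": cond.bridge_residue[0],
                        "residue_name": cond.bridge_residue[1],
                        "subunit": su,
                        "bridge_frequency": f,
                    }
                    for su, f in zip(
                        bridge.subunit_ids, bridge.per_subunit_frequency
                    )
                ]
                + [
                    {
                        "residue_seq": cond.bridge_residue[0],
                        "residue_name": cond.bridge_residue[1],
                        "subunit": "combined",
                        "bridge_frequency": bridge.bridge_frequency,
                    }
                ]
            )
            summary.to_csv(
                paths["waterbridge"], sep="\t", index=False,
                float_format="%.6f",
            )
        artefacts[cond.label] = paths

    for a, b in config.selectivity_pairs:
        name = f"selectivity_{a}_vs_{b}"
        report = _stage(
            "selectivity",
            name,
            lambda: classify_selectivity(
                profiles[a], profiles[b],
                threshold=config.selectivity_threshold,
            ),
            timings,
        )
        path = out_root / f"{name}.tsv"
        report.to_frame().to_csv(
            path, sep="\t", index=False, float_format="%.6f"
        )
        artefacts.setdefault("_pairs", {})[name] = path

    _write_summary(config, artefacts, out_root)
    with open(out_root / "pipeline.log", "w") as fh:
        for name, elapsed in timings:
            fh.write(f"{name}\t{elapsed:.3f}s\n")
    return artefacts


def _write_summary(
    config: PipelineConfig,
    artefacts: dict[str, dict[str, Path]],
    out_root: Path,
) -> None:
    lines = [
        "ligprof pipeline summary",
        f"seed: {config.seed}",
        f"contact_cutoff_A: {config.contact_cutoff}",
        f"selectivity_threshold: {config.selectivity_threshold}",
        f"water_cutoff_A: {config.water_cutoff}",
        f"bridge_distance_A: {config.bridge_distance}",
        f"map_resolution_A: {config.resolution}",
        f"atom_size_A: {config.atom_size}",
        f"rmsd_mode: {config.rmsd_mode}",
        "",
    ]
    for label, paths in sorted(artefacts.items()):
        for name, path in sorted(paths.items()):
            lines.append(f"{label}/{name}: {path.relative_to(out_root)}")
    (out_root / "summary.txt").write_text("\n".join(lines) + "\n")
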