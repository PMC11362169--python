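"""End-to-end orchestration: configured, logged, reproducible runs.

``run_hdx_pipeline`` chains parse → filter → uptake → summarize →
two-stage test → residue map and writes a self-describing output bundle:
result CSVs, a JSON audit log with record counts at every stage, and a
provenance block (config, seed, package versions, SHA-256 of every input)
sufficient to re-run the analysis bit-exactly.  ``run_structure_report``
does the same for a two-conformation geometry comparison.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, hdx_io, hdx_stats
from .geometry import (compute_dihedrals, dihedral_difference, helix_axis,
                       inter_helix_angle, screw_decompose, site_displacement,
                       superpose)
from .structure import ResidueSelection, read_structure

log = logging.getLogger("hdxconf")

__all__ = ["RunConfig", "run_hdx_pipeline", "run_structure_report"]


@dataclass
class RunConfig:
    """Parameters of an HDX differential run.

    Defaults mirror the module defaults; the config is serialised into the
    output directory so that re-running from it reproduces all
    deterministic outputs bit-exactly.
    """

    input_table: str
    state_a: str
    state_b: str
    out_dir: str
    protein_length: int | None = None
    min_score: float = 6.0
    min_replicates: int = 3
    n_replicates: int = 4
    filter_mode: str = "reference"
    ci1: float = 0.95
    ci2: float = 0.99
    pooling: str = "quadrature"
    df_stage2: int | None = None
    aggregation: str = "mean"
    column_map: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _provenance(config, inputs) -> dict:
    import gemmi, scipy  # noqa: F401  (versions recorded below)

    return {
        "hdxconf_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "seed": getattr(config, "seed", None),
        "config": asdict(config) if hasattr(config, "__dataclass_fields__") else dict(config),
        "input_checksums": {str(p): _sha256(p) for p in inputs},
    }


def run_hdx_pipeline(config: RunConfig) -> dict:
    """Run the full differential HDX analysis described by ``config``.

    Returns a bundle dict with stage-wise counts and paths of everything
    written.  Any stage failure raises with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"stages": {}}

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s ...", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    table = stage("parse", hdx_io.read_state_table, config.input_table,
                  config.column_map or None)
    bundle["stages"]["parsed_rows"] = len(table)
    bundle["stages"]["rejected_rows"] = len(table.rejected)

    table, _ = stage("filter", hdx_io.filter_peptides, table,
                     min_score=config.min_score,
                     min_replicates=config.min_replicates,
                     n_replicates=config.n_replicates,
                     mode=config.filter_mode)
    bundle["stages"]["peptides_after_filter"] = len(table.peptides)

    if len(table.peptides) == 0:
        result = hdx_stats.DifferentialResult(
            pd.DataFrame(columns=hdx_io.PEPTIDE_KEY + ["sum_dD", "significant"]),
            pd.DataFrame(), {"zero_results": True})
        bundle["zero_results"] = True
        bundle["stages"]["peptides_tested"] = 0
        bundle["stages"]["peptides_significant"] = 0
    else:
        table = stage("uptake", hdx_io.uptake_from_centroids, table)
        summary = stage("summarize", hdx_stats.summarize, table)
        for state in (config.state_a, config.state_b):
            if state not in set(summary["state"]):
                raise RuntimeError(f"pipeline stage 'summarize' failed: state {state!r} "
                                   f"not present (have {sorted(set(summary['state']))})")

        result = stage("two_stage_test", hdx_stats.two_stage_test,
                       summary[summary["state"] == config.state_a],
                       summary[summary["state"] == config.state_b],
                       ci1=config.ci1, ci2=config.ci2, pooling=config.pooling,
                       df_stage2=config.df_stage2)
        bundle["stages"]["peptides_tested"] = len(result.peptides)
        bundle["stages"]["peptides_significant"] = result.n_significant

    length = config.protein_length or (int(table.data["end"].max()) if len(table) else 0)
    residue_map = stage("residue_map", hdx_stats.residue_level_map,
                        result, length, aggregation=config.aggregation)

    paths = {
        "differential": out / "differential_peptides.csv",
        "exposures": out / "differential_exposures.csv",
        "residue_map": out / "residue_map.csv",
        "audit": out / "audit.json",
        "config": out / "config.yaml",
        "provenance": out / "provenance.json",
    }
    result.peptides.to_csv(paths["differential"], index=False)
    result.exposures.to_csv(paths["exposures"], index=False)
    residue_map.to_csv(paths["residue_map"])
    table.audit.extend(result.audit)
    table.note("bundle", **bundle["stages"])
    table.write_audit(paths["audit"])
    config.to_yaml(paths["config"])
    paths["provenance"].write_text(
        json.dumps(_provenance(config, [config.input_table]), indent=2) + "\n")
    bundle["paths"] = {k: str(v) for k, v in paths.items()}
    bundle["params"] = result.params
    return bundle


def run_structure_report(path_a, path_b, selections: dict,
                         out_path=None) -> dict:
    """Geometry comparison report for two conformations of one protein.

    ``selections`` maps names to selection strings and must contain
    ``scaffold``, ``transport``, and ``linkers`` (list of strings); it may
    contain ``site`` (binding-site residues), ``helix_pairs`` (list of
    two-string lists for inter-helix angles), and ``normal`` (3-vector or
    "auto").  Unresolvable selections halt with the offending names listed.
    """
    a = read_structure(path_a)
    b = read_structure(path_b)

    parsed = {}
    bad = []
    flat = {"scaffold": selections["scaffold"], "transport": selections["transport"]}
    for i, text in enumerate(selections.get("linkers", [])):
        flat[f"linker_{i}"] = text
    if "site" in selections:
        flat["site"] = selections["site"]
    for j, pair in enumerate(selections.get("helix_pairs", [])):
        flat[f"helix_{j}a"], flat[f"helix_{j}b"] = pair
    for name, text in flat.items():
        sel = ResidueSelection.parse(text)
        for st, label in ((a, "A"), (b, "B")):
            try:
                sel.mask(st)
            except ValueError:
                bad.append(f"{name} ({text}) in structure {label}")
        parsed[name] = sel
    if bad:
        raise ValueError("unresolvable selections: " + "; ".join(bad))

    report: dict = {"structure_a": str(path_a), "structure_b": str(path_b)}
    for name in ("scaffold", "transport"):
        _, rmsd, n = superpose(b, a, parsed[name])
        report[f"rmsd_{name}"] = rmsd
        report[f"n_atoms_{name}"] = n

    # dihedral differences over the linker selections
    linkers = [parsed[k] for k in parsed if k.startswith("linker_")]
    dihedrals = {}
    for i, sel in enumerate(linkers):
        bb = sel.with_atoms(("N", "CA", "C"))
        series_a = compute_dihedrals(a.select(bb))
        series_b = compute_dihedrals(b.select(bb))
        diff = dihedral_difference(series_a, series_b)
        dihedrals[f"linker_{i}"] = diff
        valid = diff[["dphi", "dpsi"]].max(axis=1)
        report[f"linker_{i}_max_dihedral_change"] = float(valid.max())
    report["_dihedral_tables"] = dihedrals

    # transport-domain screw in the scaffold frame
    align, _, _ = superpose(b, a, parsed["scaffold"])
    b_aligned = b.transformed(align.rotation, align.translation)
    motion, _, _ = superpose(a, b_aligned, parsed["transport"])
    screw = screw_decompose(motion)
    report["transport_rotation_angle"] = screw.angle
    report["transport_rotation_pitch"] = screw.pitch
    report["transport_rotation_axis"] = (screw.axis.tolist()
                                         if screw.axis is not None else None)

    if "site" in parsed:
        normal = selections.get("normal", "auto")
        total, along = site_displacement(a, b, parsed["scaffold"], parsed["site"],
                                         normal=normal)
        report["site_displacement_total"] = total
        report["site_displacement_along_normal"] = along

    for j in range(len(selections.get("helix_pairs", []))):
        for st, label in ((a, "a"), (b, "b")):
            acute, _ = inter_helix_angle(helix_axis(st, parsed[f"helix_{j}a"]),
                                         helix_axis(st, parsed[f"helix_{j}b"]))
            report[f"helix_pair_{j}_angle_{label}"] = acute
        report[f"helix_pair_{j}_angle_change"] = (
            report[f"helix_pair_{j}_angle_a"] - report[f"helix_pair_{j}_angle_b"])

    if out_path is not None:
        serialisable = {k: v for k, v in report.items() if not k.startswith("_")}
        Path(out_path).write_text(json.dumps(serialisable, indent=2) + "\n")
    return report
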