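"""Deposited-structure analyses for the UraA conformational series.

These helpers reproduce the headline geometry of the UraA conformational
comparison from locally supplied coordinate files: domain superposition
RMSDs between the wide inward-open, inward-open, and occluded states,
binding-site elevation after scaffold alignment, the external spacer-helix
vs TM11 angle change, and the buried sybody epitope area.

Coordinate files are **not** bundled: download the PDB entries (8OMZ —
wide inward-open UraA(G320P)–Sy45 complex; 5XLS — occluded; 3QE7 —
inward-open; optionally 5I6C — inward-facing UapA) into a directory and
point :func:`deposited_structure_report` at it.  The shipped domain
definitions are reconstructions (see ``data/uraa_domains.yaml``) and can
be overridden.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml

from .geometry import (helix_axis, inter_helix_angle, screw_decompose,
                       site_displacement, superpose)
from .structure import ResidueSelection, StructureModel, read_structure
from .surface import buried_surface_area, contact_residues

__all__ = [
    "load_domain_config",
    "domain_selection",
    "deposited_structure_report",
]

#: the deposited entries this analysis expects, by role
ENTRY_ROLES = {
    "wide_inward_open": "8OMZ",
    "occluded": "5XLS",
    "inward_open": "3QE7",
}


def load_domain_config(path=None) -> dict:
    """Load the packaged (reconstructed) UraA domain definitions, or a
    user-supplied YAML with the same layout."""
    if path is not None:
        text = Path(path).read_text()
    else:
        text = (importlib.resources.files("hdxconf") / "data" / "uraa_domains.yaml").read_text()
    return yaml.safe_load(text)


def domain_selection(config: dict, domain: str, chain: str | None = None,
                     atoms=("CA",)) -> ResidueSelection:
    """Build a :class:`ResidueSelection` for a named domain, TM segment, or
    other range entry of the domain config."""
    chain = chain or config["chain"]
    if domain in config.get("domains", {}):
        tms = config["domains"][domain]
        ranges = tuple((chain, *config["transmembrane"][tm]) for tm in tms)
    elif domain in config.get("transmembrane", {}):
        ranges = ((chain, *config["transmembrane"][domain]),)
    elif domain in config.get("linkers", {}):
        ranges = ((chain, *config["linkers"][domain]),)
    elif domain in config.get("spacer_helices", {}):
        ranges = ((chain, *config["spacer_helices"][domain]),)
    elif domain == "binding_site":
        ranges = tuple((chain, r, r) for r in config["binding_site"])
    else:
        raise KeyError(f"no entry {domain!r} in domain config")
    return ResidueSelection(ranges, atoms=tuple(atoms) if atoms else None)


def _find_entry(directory: Path, code: str) -> Path:
    for suffix in (".cif", ".pdb", ".cif.gz", ".ent"):
        for name in (code.upper(), code.lower()):
            p = directory / f"{name}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(
        f"deposited entry {code} not found under {directory}; download it "
        f"from the PDB (e.g. {code.upper()}.cif) and place it there")


def deposited_structure_report(structure_dir, config: dict | None = None,
                               uraa_chain: str | None = None,
                               sybody_chain: str = "B",
                               membrane_normal="auto") -> dict:
    """Compute the conformational-comparison metrics from local PDB entries.

    Parameters
    ----------
    structure_dir
        Directory containing 8OMZ / 5XLS / 3QE7 coordinate files.
    config
        Domain definitions; defaults to the packaged reconstruction.
    uraa_chain, sybody_chain
        Chain ids of the transporter and the sybody in the complex entry.
    membrane_normal
        Normal vector for the elevation component, or ``"auto"`` to derive
        it from the dimer two-fold when the complex entry is dimeric.

    Returns a flat dict of metrics (RMSDs in Å, angles in degrees, areas
    in Å²).
    """
    directory = Path(structure_dir)
    config = config or load_domain_config()
    chain = uraa_chain or config["chain"]

    wio = read_structure(_find_entry(directory, ENTRY_ROLES["wide_inward_open"]))
    occ = read_structure(_find_entry(directory, ENTRY_ROLES["occluded"]))
    io = read_structure(_find_entry(directory, ENTRY_ROLES["inward_open"]))

    transport = domain_selection(config, "transport", chain=chain)
    scaffold = domain_selection(config, "scaffold", chain=chain)
    site = domain_selection(config, "binding_site", chain=chain)
    tm11 = domain_selection(config, "TM11", chain=chain)
    spacer_ext = domain_selection(config, "external", chain=chain)

    report: dict = {}
    _, report["rmsd_transport_wio_vs_io"], _ = superpose(wio, io, transport)
    _, report["rmsd_transport_wio_vs_occ"], _ = superpose(wio, occ, transport)
    _, report["rmsd_scaffold_wio_vs_occ"], _ = superpose(wio, occ, scaffold)

    total, along = site_displacement(occ, wio, align_on=scaffold, site=site,
                                     normal=membrane_normal)
    report["site_elevation_total"] = total
    report["site_elevation_along_normal"] = along

    for label, st in (("wio", wio), ("occ", occ)):
        angle_acute, _ = inter_helix_angle(helix_axis(st, spacer_ext),
                                           helix_axis(st, tm11))
        report[f"spacer_tm11_angle_{label}"] = angle_acute
    report["spacer_tm11_angle_change"] = (report["spacer_tm11_angle_wio"]
                                          - report["spacer_tm11_angle_occ"])

    # rigid-body screw of the transport domain in the scaffold frame
    align, _, _ = superpose(occ, wio, scaffold)
    occ_aligned = occ.transformed(align.rotation, align.translation)
    motion, _, _ = superpose(wio, occ_aligned, transport)
    screw = screw_decompose(motion)
    report["transport_rotation_angle"] = screw.angle
    report["transport_rotation_pitch"] = screw.pitch

    # sybody epitope on the complex entry
    complex_all = read_structure(_find_entry(directory,
                                             ENTRY_ROLES["wide_inward_open"]))
    area_uraa, area_sybody = buried_surface_area(complex_all, [chain],
                                                 [sybody_chain])
    report["epitope_buried_area_uraa"] = area_uraa
    report["epitope_buried_area_sybody"] = area_sybody
    contacts = contact_residues(complex_all, [sybody_chain], [chain], cutoff=4.0)
    report["n_epitope_residues"] = len(contacts.ranges) if contacts else 0
    return report
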