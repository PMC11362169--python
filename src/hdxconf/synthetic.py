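"""Synthetic ground-truth generators for every pipeline input.

Four generators cover the pipeline's input classes:

* EX2 hydrogen-deuterium exchange: per-residue deuteration follows
  ``D_i(t) = (1 − bx)·(1 − exp(−k_int,i · 10^{−logPF_i} · t))`` with
  state-dependent protection factors, projected onto a redundant peptide
  map and read out as noisy centroid masses over the labeling time course
  (default 0/30/360/900/2700 s, four replicates).
* Toy two-helix structures related by a known hinge rotation, built
  analytically so dihedral/superposition/screw machinery can be checked
  against exact ground truth.
* Homologous-competition binding curves (scintillation counts vs unlabeled
  competitor concentration).
* Thermal melting curves (sigmoid fluorescence vs temperature).

Every generator takes a seed and is bit-reproducible; ground truth is
returned as a :class:`SyntheticTruth` alongside the dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hdx_io
from .chainbuild import build_backbone
from .geometry import screw_compose
from .structure import StructureModel

__all__ = [
    "ExchangeModel",
    "PeptideMap",
    "SyntheticTruth",
    "intrinsic_rates",
    "simulate_uptake_table",
    "generate_peptide_map",
    "make_toy_hinge_structures",
    "simulate_binding_curve",
    "simulate_melt_curve",
    "two_state_exchange_model",
    "DEFAULT_EXPOSURES",
]

#: labeling time course (s): reference plus four labeled exposures
DEFAULT_EXPOSURES = (0.0, 30.0, 360.0, 900.0, 2700.0)
#: replicate count of the emulated experimental design
DEFAULT_REPLICATES = 4
#: Gaussian SD of centroid noise (Da) typical of a well-behaved peptide
DEFAULT_NOISE_SD = 0.1
#: deuterium lost to back-exchange during quench and chromatography
DEFAULT_BACK_EXCHANGE = 0.25
#: default intrinsic amide exchange rate (s^-1); the simulator uses a
#: configurable per-residue-type lookup rather than full sequence-dependent
#: (Bai–Englander) rates
DEFAULT_K_INT = 1.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters paired with a generated dataset."""

    params: dict
    seed: int

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        Path(path).write_text(
            json.dumps({"seed": self.seed, **self.params}, indent=2,
                       default=default) + "\n")


def intrinsic_rates(sequence: str, table: dict | None = None,
                    default: float = DEFAULT_K_INT) -> np.ndarray:
    """Per-residue intrinsic exchange rates from a residue-type lookup.

    Prolines get rate 0 (no amide hydrogen); all other residues take the
    rate from ``table`` (one-letter code -> s⁻¹) or ``default``.
    """
    table = table or {}
    rates = np.array([0.0 if aa == "P" else float(table.get(aa, default))
                      for aa in sequence.upper()])
    return rates


@dataclass(frozen=True)
class ExchangeModel:
    """Per-residue EX2 exchange model with state-dependent protection.

    ``k_int`` are intrinsic rates (s⁻¹, zero only at prolines);
    ``logpf_by_state`` maps each state name to per-residue log10 protection
    factors (≥ 0); ``back_exchange`` is the deuterium fraction lost before
    measurement, in [0, 1).
    """

    sequence: str
    k_int: np.ndarray
    logpf_by_state: dict
    back_exchange: float = DEFAULT_BACK_EXCHANGE

    def __post_init__(self):
        seq = self.sequence.upper()
        bad = set(seq) - hdx_io.VALID_AA
        if bad:
            raise ValueError(f"non-standard residue code(s): {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        k = np.asarray(self.k_int, float)
        if len(k) != len(seq):
            raise ValueError("k_int length must match sequence length")
        is_pro = np.array([aa == "P" for aa in seq])
        if np.any(k[~is_pro] <= 0) or np.any(k[is_pro] != 0):
            raise ValueError("k_int must be > 0 except exactly 0 at prolines")
        object.__setattr__(self, "k_int", k)
        if not 0 <= self.back_exchange < 1:
            raise ValueError("back_exchange must be in [0, 1)")
        states = {}
        for state, logpf in self.logpf_by_state.items():
            lp = np.asarray(logpf, float)
            if len(lp) != len(seq) or np.any(lp < 0):
                raise ValueError(f"logPF for state {state!r} invalid")
            states[state] = lp
        object.__setattr__(self, "logpf_by_state", states)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def deuteration(self, state: str, t: float) -> np.ndarray:
        """Per-residue deuterium fraction D_i(t); prolines are always 0."""
        logpf = self.logpf_by_state[state]
        k_obs = self.k_int * np.power(10.0, -logpf)
        d = (1.0 - self.back_exchange) * -np.expm1(-k_obs * t)
        is_pro = np.array([aa == "P" for aa in self.sequence])
        d[is_pro] = 0.0
        return d

    def peptide_uptake(self, state: str, start: int, end: int, t: float) -> float:
        """True uptake (Da) of a peptide spanning 1-based ``start..end``:
        sum of D_i over residues ``start+1..end`` excluding prolines (the
        first residue loses its label to fast back-exchange)."""
        d = self.deuteration(state, t)
        return float(d[start:end].sum())  # slice start..end-1 0-based == start+1..end


@dataclass(frozen=True)
class PeptideMap:
    """Overlapping peptide intervals over a protein sequence.

    ``peptides`` is a list of ``(start, end, subsequence)`` with 1-based
    inclusive coordinates.
    """

    peptides: tuple
    protein_length: int

    def __post_init__(self):
        for start, end, seq in self.peptides:
            if not (1 <= start <= end <= self.protein_length):
                raise ValueError(f"peptide {start}-{end} outside protein "
                                 f"of length {self.protein_length}")
            if len(seq) != end - start + 1:
                raise ValueError(f"peptide {start}-{end} sequence length mismatch")

    def __len__(self):
        return len(self.peptides)

    @property
    def intervals(self):
        return [(s, e) for s, e, _ in self.peptides]


def generate_peptide_map(sequence: str, mean_length: int = 10, step: int = 2,
                         seed: int = 0) -> PeptideMap:
    """Random overlapping peptide map emulating peptic digestion.

    Peptide starts advance by a random stride of mean ``step`` and lengths
    vary around ``mean_length``, giving a redundancy of roughly
    ``mean_length / step`` (the default ≈ 5 matches a well-covered membrane
    protein experiment).
    """
    n = len(sequence)
    if mean_length < 3:
        raise ValueError("mean_length must be >= 3")
    if mean_length > n:
        raise ValueError("mean_length exceeds sequence length")
    rng = np.random.default_rng(seed)
    peptides = []
    start = 1
    while start <= n - 2:
        length = int(np.clip(rng.poisson(mean_length), 3, 25))
        end = min(start + length - 1, n)
        peptides.append((start, end, sequence[start - 1:end]))
        start += int(rng.integers(1, 2 * step))
    return PeptideMap(tuple(peptides), n)


def simulate_uptake_table(model: ExchangeModel, pmap: PeptideMap,
                          exposures=DEFAULT_EXPOSURES,
                          n_replicates: int = DEFAULT_REPLICATES,
                          noise_sd: float = DEFAULT_NOISE_SD,
                          seed: int = 0,
                          protein: str = "synthetic",
                          score: float = 9.0) -> hdx_io.UptakeTable:
    """Simulate a replicate-level peptide uptake table.

    Centroid masses are the peptide monoisotopic mass plus the true EX2
    uptake plus Gaussian centroid noise (applied at the peptide level, in
    Da, matching centroid-resolution measurement).  Exposure-0 rows carry
    exactly zero uptake before noise.  The returned table parses and
    serialises through :mod:`hdxconf.hdx_io` without loss.
    """
    from pyteomics import mass as pmass

    exposures = sorted(float(t) for t in exposures)
    if 0.0 not in exposures:
        raise ValueError("exposures must include the 0 s reference")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if pmap.protein_length != model.length:
        raise ValueError("peptide map and model cover different lengths")

    rng = np.random.default_rng(seed)
    rows = []
    base_mass = {seq: pmass.fast_mass(seq) for _, _, seq in pmap.peptides}
    for state in sorted(model.logpf_by_state):
        for start, end, seq in pmap.peptides:
            for t in exposures:
                truth = model.peptide_uptake(state, start, end, t)
                noise = rng.normal(0.0, noise_sd, size=n_replicates) if noise_sd else np.zeros(n_replicates)
                for rep in range(1, n_replicates + 1):
                    rows.append((protein, start, end, seq, state, t, rep,
                                 base_mass[seq] + truth + noise[rep - 1],
                                 score, hdx_io.max_uptake(seq)))
    df = pd.DataFrame(rows, columns=["protein", "start", "end", "sequence",
                                     "state", "exposure", "replicate",
                                     "centroid", "score", "max_uptake"])
    table = hdx_io.UptakeTable(df)
    table.note("simulate_uptake_table", seed=seed, noise_sd=noise_sd,
               n_replicates=n_replicates, exposures=exposures,
               peptides=len(pmap), states=list(sorted(model.logpf_by_state)))
    return table


def two_state_exchange_model(length: int = 300, frac_affected: float = 0.2,
                             delta_logpf: float = 1.0, seed: int = 0,
                             state_a: str = "reference", state_b: str = "variant",
                             back_exchange: float = DEFAULT_BACK_EXCHANGE,
                             block_length: int = 15):
    """Convenience: a two-state model with protected contiguous segments.

    State B adds ``delta_logpf`` to the baseline log protection factor of
    contiguous blocks of residues (~``block_length`` long, as protection
    changes in a folded protein span secondary-structure elements, not
    scattered single residues) totalling a fraction ``frac_affected`` of the
    protein (positive = more protected = less uptake).  Baseline logPF ~
    U[2, 3.5], which with the default 1 s⁻¹ intrinsic rate gives observed
    exchange timescales of 100–3300 s, inside the sampled labeling window.
    Returns ``(ExchangeModel, SyntheticTruth)``.
    """
    rng = np.random.default_rng(seed)
    # avoid prolines so every residue is informative
    alphabet = np.array(list("ACDEFGHIKLMNQRSTVWY"))
    sequence = "".join(rng.choice(alphabet, size=length))
    base = rng.uniform(2.0, 3.5, size=length)
    affected = np.zeros(length, dtype=bool)
    n_aff = int(round(frac_affected * length))
    if n_aff:
        n_blocks = max(1, round(n_aff / block_length))
        sizes = np.full(n_blocks, n_aff // n_blocks)
        sizes[:n_aff % n_blocks] += 1
        # place blocks left to right in randomly sized gaps
        free = length - n_aff
        if free < n_blocks:
            raise ValueError("frac_affected too large for block placement")
        gaps = rng.multinomial(free - n_blocks, np.ones(n_blocks + 1) / (n_blocks + 1))
        pos = 0
        for k, size in enumerate(sizes):
            pos += gaps[k] + (1 if k > 0 else 0)
            affected[pos:pos + size] = True
            pos += size
    delta = np.where(affected, delta_logpf, 0.0)
    model = ExchangeModel(
        sequence=sequence,
        k_int=intrinsic_rates(sequence),
        logpf_by_state={state_a: base, state_b: base + delta},
        back_exchange=back_exchange,
    )
    truth = SyntheticTruth(
        params={"kind": "two_state_exchange", "length": length,
                "delta_logpf": delta.tolist(), "affected": affected.tolist(),
                "base_logpf": base.tolist(), "state_a": state_a,
                "state_b": state_b, "back_exchange": back_exchange},
        seed=seed)
    return model, truth


# ---------------------------------------------------------------------------
# toy hinge structures
# ---------------------------------------------------------------------------

def make_toy_hinge_structures(n_res_per_helix: int = 12,
                              hinge_angle: float = 25.0,
                              hinge_axis=(0.0, 0.0, 1.0),
                              seed: int = 0,
                              phi: float = -57.0, psi: float = -47.0):
    """Two ideal helices with a known hinge rotation between them.

    Structure A is a continuous 2N-residue α-helical backbone built from
    internal coordinates.  Structure B is A with all atoms of the second
    helix (residues N+1..2N) rigidly rotated by ``hinge_angle`` degrees
    about ``hinge_axis`` through the backbone N of residue N+1 (the pivot
    atom).  By construction, dihedral differences are confined to the pivot
    residues N and N+1, and the second-helix superposition transform has
    exactly the requested screw parameters.

    Returns ``(A, B, SyntheticTruth)``.
    """
    axis = np.asarray(hinge_axis, float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("degenerate (zero) hinge axis")
    axis = axis / np.linalg.norm(axis)
    if not 0.0 <= hinge_angle < 180.0:
        raise ValueError("hinge_angle must be in [0, 180)")
    n = int(n_res_per_helix)
    if n < 4:
        raise ValueError("need at least 4 residues per helix")

    total = 2 * n
    a = build_backbone(np.full(total, phi), np.full(total, psi),
                       label="hinge_A")
    pivot = a.atom_coord("A", n + 1, "N")
    if hinge_angle == 0.0:
        b = StructureModel(a.atoms.copy(), label="hinge_B")
    else:
        transform = screw_compose(axis, hinge_angle, pitch=0.0, point=pivot)
        moving = (a.atoms["resnum"] > n).to_numpy()
        df = a.atoms.copy()
        xyz = df.loc[moving, ["x", "y", "z"]].to_numpy(float)
        df.loc[moving, ["x", "y", "z"]] = transform.apply(xyz)
        b = StructureModel(df, label="hinge_B")

    truth = SyntheticTruth(
        params={"kind": "toy_hinge", "n_res_per_helix": n,
                "hinge_angle": float(hinge_angle), "hinge_axis": axis,
                "pivot": pivot, "phi": phi, "psi": psi},
        seed=seed)
    return a, b, truth


# ---------------------------------------------------------------------------
# assay curves
# ---------------------------------------------------------------------------

def homologous_competition_model(cold, hot: float, kd: float,
                                 bmax: float, background: float):
    """Expected counts: ``Bmax·[hot] / ([hot] + [cold] + Kd) + background``."""
    cold = np.asarray(cold, float)
    return bmax * hot / (hot + cold + kd) + background


def simulate_binding_curve(kd: float = 600.0, bmax: float = 1000.0,
                           background: float = 100.0, hot_conc: float = 34.0,
                           cold_concs=None, noise_sd: float | None = None,
                           noise_frac: float = 0.05,
                           n_replicates: int = 3, seed: int = 0):
    """Noisy homologous-competition scintillation counts.

    Concentrations in nM, counts in CPM.  Defaults emulate a wild-type
    uracil binding series (34 nM hot ligand, µM-range competitor ladder).
    Noise is Gaussian with SD ``noise_sd`` CPM, or — since counting noise
    scales with the measured signal — ``noise_frac`` of the curve's dynamic
    range when ``noise_sd`` is None (default 5%).
    Returns ``(DataFrame[cold_nM, replicate, cpm], SyntheticTruth)``.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if hot_conc < 0:
        raise ValueError("concentrations must be non-negative")
    if cold_concs is None:
        cold_concs = np.concatenate([[0.0], np.geomspace(1.0, 1e6, 12)])
    cold_concs = np.asarray(cold_concs, float)
    if np.any(cold_concs < 0):
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    truth_cpm = homologous_competition_model(cold_concs, hot_conc, kd, bmax, background)
    if noise_sd is None:
        noise_sd = noise_frac * (truth_cpm.max() - truth_cpm.min())
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rows = []
    for rep in range(1, n_replicates + 1):
        noisy = truth_cpm + (rng.normal(0, noise_sd, size=len(cold_concs))
                             if noise_sd else 0.0)
        rows.append(pd.DataFrame({"cold_nM": cold_concs, "replicate": rep,
                                  "cpm": noisy}))
    data = pd.concat(rows, ignore_index=True)
    truth = SyntheticTruth(params={"kind": "binding", "kd": kd, "bmax": bmax,
                                   "background": background, "hot_conc": hot_conc},
                           seed=seed)
    return data, truth


def simulate_melt_curve(tm: float = 60.0, slope: float = 2.0,
                        baselines=(100.0, 1000.0), noise_sd: float = 5.0,
                        seed: int = 0, t_range=(25.0, 90.0), t_step: float = 0.5):
    """Noisy thermal melting curve (logistic sigmoid between baselines).

    Temperature ramp defaults to 25–90 °C sampled every 0.5 °C.  ``slope``
    is the logistic width in °C.  Returns
    ``(DataFrame[temperature_C, fluorescence], SyntheticTruth)``.
    """
    lo, hi = t_range
    if not lo < tm < hi:
        raise ValueError("Tm must lie within the temperature ramp")
    if slope <= 0:
        raise ValueError("slope must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    temps = np.arange(lo, hi + t_step / 2, t_step)
    f_lo, f_hi = baselines
    truth_f = f_lo + (f_hi - f_lo) / (1.0 + np.exp(-(temps - tm) / slope))
    noisy = truth_f + (rng.normal(0, noise_sd, size=len(temps)) if noise_sd else 0.0)
    data = pd.DataFrame({"temperature_C": temps, "fluorescence": noisy})
    truth = SyntheticTruth(params={"kind": "melt", "tm": tm, "slope": slope,
                                   "baselines": list(baselines)},
                           seed=seed)
    return data, truth
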