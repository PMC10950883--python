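"""Ground-truthed synthetic data for the nitrotyrosine enrichment pipeline.

The generator emulates the statistical structure the downstream analyses
assume, not the chemistry that produces it: a random proteome, tyrosines
nitrated with a susceptibility bonus when small non-polar residues
(G, L, P, A, E) flank them, tryptic digestion with missed cleavages,
antibody capture in two enrichment modes — protein-level capture (no
positional bias) and peptide-level capture (boosted for peptides whose
nitroY sits at position 1, calibrated so the per-antibody fraction of
N-terminal nitro peptidoforms equals that antibody's bias parameter) —
and b/y fragment spectra with a shared intensity draw between each
noisy "experimental" spectrum and its clean "synthetic" twin, so the noise
parameters alone drive cosine-score degradation.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .masses import (
    DEFAULT_MODIFICATIONS,
    ConfigurationError,
    InputError,
    Peptidoform,
    fragment_series,
    precursor_mz,
)
from .spectra import PSMRecord, Spectrum, write_fasta, write_mgf, write_psm_table

__all__ = [
    "AntibodyConfig",
    "SimulationConfig",
    "GroundTruth",
    "NitropeptideCandidate",
    "ValidationSet",
    "SWISSPROT_FREQUENCIES",
    "generate_proteome",
    "digest_trypsin",
    "assign_nitration_sites",
    "nitropeptide_candidates",
    "simulate_capture",
    "simulate_spectrum",
    "simulate_spectrum_pair",
    "generate_validation_set",
]

#: Average amino-acid frequencies of reviewed UniProtKB entries (percent,
#: renormalized at use); the default residue background of the simulator.
SWISSPROT_FREQUENCIES: Mapping[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.65, "T": 5.36, "W": 1.10, "Y": 2.92, "V": 6.86,
}


@dataclass(frozen=True)
class AntibodyConfig:
    """One anti-nitrotyrosine antibody: capture efficiency and N-terminal bias.

    ``p_nterm_bias`` is the expected fraction of captured distinct nitro
    peptidoforms with the nitroY at peptide position 1 in peptide-level mode;
    it has no effect in protein-level mode.
    """

    name: str
    capture_probability: float = 0.7
    p_nterm_bias: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.capture_probability <= 1:
            raise ConfigurationError(f"{self.name}: capture_probability not in (0, 1]")
        if not 0 < self.p_nterm_bias < 1:
            raise ConfigurationError(f"{self.name}: p_nterm_bias not in (0, 1)")


def _default_antibodies() -> tuple[AntibodyConfig, ...]:
    # Four commercial antibodies; peptide-mode N-terminal biases span the
    # 35-65% range seen across antibodies, capture efficiencies differ so
    # the overlap structure has both shared and antibody-specific captures.
    return (
        AntibodyConfig("AB1", capture_probability=0.60, p_nterm_bias=0.35),
        AntibodyConfig("AB2", capture_probability=0.80, p_nterm_bias=0.45),
        AntibodyConfig("AB3", capture_probability=0.65, p_nterm_bias=0.55),
        AntibodyConfig("AB4", capture_probability=0.70, p_nterm_bias=0.65),
    )


@dataclass
class SimulationConfig:
    """All tunables of the generator; defaults define the study-like conditions."""

    seed: int = 0
    n_proteins: int = 300
    protein_length_mean: float = 450.0
    protein_length_sd: float = 150.0
    protein_length_min: int = 50
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(SWISSPROT_FREQUENCIES)
    )
    # nitration: per-Y base probability, multiplied by the context bonus when
    # any of the context residues occurs within +/- context_halfwidth
    nitration_base_rate: float = 0.05
    nitration_context_bonus: float = 3.0
    context_residues: str = "GLPAE"
    context_halfwidth: int = 2
    # capture
    antibodies: tuple[AntibodyConfig, ...] = field(default_factory=_default_antibodies)
    replicates: int = 3
    # digestion
    missed_cleavage_max: int = 2
    peptide_length_bounds: tuple[int, int] = (6, 30)
    proline_rule: bool = True
    # spectra
    precursor_charge: int = 2
    max_fragment_charge: int = 2
    charge2_fragment_mass_min: float = 900.0
    fragment_intensity_sigma: float = 0.8
    peak_dropout_probability: float = 0.10
    mz_jitter_sd: float = 0.002
    intensity_noise_cv: float = 0.25
    n_contaminant_peaks: int = 5
    # validation set
    decoy_fraction: float = 0.3

    def __post_init__(self) -> None:
        for name in (
            "nitration_base_rate",
            "peak_dropout_probability",
            "intensity_noise_cv",
            "decoy_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.nitration_context_bonus < 0:
            raise ConfigurationError("nitration_context_bonus must be >= 0")
        if not self.antibodies:
            raise ConfigurationError("at least one antibody required")
        probs = np.array([self.background.get(aa, 0.0) for aa in SWISSPROT_FREQUENCIES])
        if probs.sum() <= 0 or (probs < 0).any():
            raise ConfigurationError("degenerate residue background frequencies")
        self.antibodies = tuple(
            a if isinstance(a, AntibodyConfig) else AntibodyConfig(**a)
            for a in self.antibodies
        )

    def rng(self, *streams: int) -> np.random.Generator:
        """A generator for an independent, reproducible substream of this seed."""
        return np.random.default_rng((self.seed, *streams))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: nitration sites and validation-pair truth."""

    sites: Mapping[str, tuple[int, ...]]
    pair_is_decoy: Mapping[str, bool] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "sites": {acc: list(pos) for acc, pos in self.sites.items()},
            "pair_is_decoy": dict(self.pair_is_decoy),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def generate_proteome(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Random i.i.d.-residue proteome: ``{SYNxxxx: sequence}``."""
    alphabet = np.frombuffer("".join(SWISSPROT_FREQUENCIES).encode(), dtype=np.uint8)
    probs = np.array([float(cfg.background.get(aa, 0.0)) for aa in SWISSPROT_FREQUENCIES])
    if probs.sum() <= 0:
        raise ConfigurationError("degenerate residue background frequencies")
    probs = probs / probs.sum()
    lengths = np.maximum(
        cfg.protein_length_min,
        rng.normal(cfg.protein_length_mean, cfg.protein_length_sd, cfg.n_proteins),
    ).astype(int)
    letters = rng.choice(alphabet, size=int(lengths.sum()), p=probs)
    out: dict[str, str] = {}
    offset = 0
    for i, L in enumerate(lengths):
        out[f"SYN{i + 1:05d}"] = letters[offset : offset + L].tobytes().decode()
        offset += L
    return out


def digest_trypsin(
    sequence: str,
    missed_cleavage_max: int = 2,
    length_bounds: tuple[int, int] = (6, 30),
    proline_rule: bool = True,
) -> list[tuple[str, int]]:
    """In-silico tryptic peptides with 1-based start positions.

    Cleaves C-terminal to K/R, suppressed before proline when the proline
    rule is on; emits every product with 0..missed_cleavage_max missed
    cleavages whose length falls within ``length_bounds``.
    """
    n = len(sequence)
    cuts = [0]
    for i, c in enumerate(sequence):
        if c in "KR" and i + 1 < n and not (proline_rule and sequence[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(n)
    lo, hi = length_bounds
    out: list[tuple[str, int]] = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavage_max, len(cuts))):
            s, e = cuts[a], cuts[b]
            if lo <= e - s <= hi:
                out.append((sequence[s:e], s + 1))
    return out


def assign_nitration_sites(
    fasta: Mapping[str, str], cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, tuple[int, ...]]:
    """Independent per-tyrosine nitration with a flanking-context bonus.

    Each Y is nitrated with probability ``base_rate``, multiplied by
    ``context_bonus`` when any context residue (G/L/P/A/E by default) occurs
    within ``context_halfwidth`` residues; probabilities are capped at 1.
    Returns 1-based site positions per protein (proteins without sites omitted).
    """
    ctx = set(cfg.context_residues)
    h = cfg.context_halfwidth
    sites: dict[str, tuple[int, ...]] = {}
    for acc, seq in fasta.items():
        positions = []
        for i, r in enumerate(seq):
            if r != "Y":
                continue
            neighborhood = seq[max(0, i - h) : i] + seq[i + 1 : i + 1 + h]
            p = cfg.nitration_base_rate
            if any(c in ctx for c in neighborhood):
                p = min(1.0, p * cfg.nitration_context_bonus)
            if p > 0 and rng.random() < p:
                positions.append(i + 1)
        if positions:
            sites[acc] = tuple(positions)
    return sites


@dataclass(frozen=True)
class NitropeptideCandidate:
    """A digestible nitropeptide: one tryptic peptide x one contained site."""

    protein: str
    start: int
    sequence: str
    protein_position: int

    @property
    def peptide_position(self) -> int:
        return self.protein_position - self.start + 1

    def peptidoform(self, charge: int = 2) -> Peptidoform:
        return Peptidoform(
            self.sequence, ((self.peptide_position, "nitroY"),), charge=charge
        )

    @property
    def key(self) -> tuple[str, int]:
        """Distinct-peptidoform identity (sequence + nitro position)."""
        return (self.sequence, self.peptide_position)


def nitropeptide_candidates(
    fasta: Mapping[str, str],
    sites: Mapping[str, Sequence[int]],
    cfg: SimulationConfig,
) -> list[NitropeptideCandidate]:
    """All (tryptic peptide, contained nitration site) combinations."""
    out: list[NitropeptideCandidate] = []
    for acc, positions in sites.items():
        seq = fasta[acc]
        peptides = digest_trypsin(
            seq,
            cfg.missed_cleavage_max,
            cfg.peptide_length_bounds,
            cfg.proline_rule,
        )
        for pep, start in peptides:
            end = start + len(pep) - 1
            for pos in positions:
                if start <= pos <= end:
                    out.append(NitropeptideCandidate(acc, start, pep, pos))
    return out


def _union_probability(per_replicate: float, replicates: int) -> float:
    return 1.0 - (1.0 - per_replicate) ** replicates


def _per_replicate_probability(union: float, replicates: int) -> float:
    return 1.0 - (1.0 - union) ** (1.0 / replicates)


def _peptide_mode_probabilities(
    ab: AntibodyConfig, q1: float, replicates: int
) -> tuple[float, float]:
    """Per-replicate capture probabilities (position-1, other) for one antibody.

    Calibrated on the replicate-union capture probability so that the
    expected fraction of position-1 peptidoforms among the antibody's
    distinct captures equals ``p_nterm_bias``; the larger of the two union
    probabilities equals the antibody's nominal capture probability.
    """
    t = ab.p_nterm_bias
    if not 0 < q1 < 1:
        raise InputError(f"degenerate baseline position-1 fraction {q1}")
    r = (t * (1.0 - q1)) / ((1.0 - t) * q1)  # required odds ratio
    c_union = _union_probability(ab.capture_probability, replicates)
    if r >= 1.0:
        u1, u0 = c_union, c_union / r
    else:
        u1, u0 = c_union * r, c_union
    return (
        _per_replicate_probability(u1, replicates),
        _per_replicate_probability(u0, replicates),
    )


def simulate_capture(
    candidates: Sequence[NitropeptideCandidate],
    cfg: SimulationConfig,
    mode: str,
    rng: np.random.Generator,
) -> list[PSMRecord]:
    """Antibody-capture PSMs for one enrichment mode.

    protein_level: each nitrated protein is captured per antibody x replicate
    with the antibody's capture probability; a captured protein emits all its
    nitropeptide candidates (no positional bias).

    peptide_level: each candidate is captured independently, with the
    position-1/other probabilities calibrated against the pool's baseline
    position-1 fraction so the antibody-level expected N-terminal fraction
    equals ``p_nterm_bias``.
    """
    if mode not in ("protein_level", "peptide_level"):
        raise InputError(f"unknown enrichment mode {mode!r}")
    records: list[PSMRecord] = []
    counter = 0
    if mode == "protein_level":
        proteins = sorted({c.protein for c in candidates})
        by_protein: dict[str, list[NitropeptideCandidate]] = {}
        for c in candidates:
            by_protein.setdefault(c.protein, []).append(c)
        for ab in cfg.antibodies:
            for rep in range(1, cfg.replicates + 1):
                captured = [
                    p for p in proteins if rng.random() < ab.capture_probability
                ]
                for p in captured:
                    for c in by_protein[p]:
                        counter += 1
                        records.append(_psm(c, ab.name, mode, rep, counter, cfg))
    else:
        keys = {c.key for c in candidates}
        n1 = sum(1 for k in keys if k[1] == 1)
        q1 = n1 / len(keys) if keys else 0.0
        for ab in cfg.antibodies:
            p1, p0 = _peptide_mode_probabilities(ab, q1, cfg.replicates)
            for rep in range(1, cfg.replicates + 1):
                draws = rng.random(len(candidates))
                for c, d in zip(candidates, draws):
                    if d < (p1 if c.peptide_position == 1 else p0):
                        counter += 1
                        records.append(_psm(c, ab.name, mode, rep, counter, cfg))
    return records


def _psm(
    c: NitropeptideCandidate,
    antibody: str,
    mode: str,
    replicate: int,
    counter: int,
    cfg: SimulationConfig,
) -> PSMRecord:
    return PSMRecord(
        peptidoform=c.peptidoform(cfg.precursor_charge),
        protein_accession=c.protein,
        peptide_start=c.start,
        spectrum_id=f"{mode}.{antibody}.r{replicate}.{counter:06d}",
        antibody=antibody,
        enrichment_mode=mode,
        replicate=replicate,
    )


def _theoretical_peaks(p: Peptidoform, cfg: SimulationConfig) -> np.ndarray:
    ions = fragment_series(p, max_fragment_charge=cfg.max_fragment_charge)
    mzs = []
    for ion in ions:
        if ion.charge == 1:
            mzs.append(ion.mz)
        else:
            neutral = ion.mz * ion.charge - ion.charge * 1.007276466879
            if neutral >= cfg.charge2_fragment_mass_min:
                mzs.append(ion.mz)
    return np.array(sorted(mzs))


def _base_intensities(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.lognormal(mean=math.log(100.0), sigma=cfg.fragment_intensity_sigma, size=n)


def _perturb(
    mz: np.ndarray,
    intensity: np.ndarray,
    precursor: float,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    keep = rng.random(mz.size) >= cfg.peak_dropout_probability
    if not keep.any():
        keep[int(np.argmax(intensity))] = True
    mz, intensity = mz[keep].copy(), intensity[keep].copy()
    if cfg.mz_jitter_sd > 0:
        mz = mz + rng.normal(0.0, cfg.mz_jitter_sd, mz.size)
    if cfg.intensity_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.intensity_noise_cv**2))
        intensity = intensity * rng.lognormal(-0.5 * sigma**2, sigma, intensity.size)
    if cfg.n_contaminant_peaks > 0:
        top = max(500.0, precursor * 2.0)
        cmz = rng.uniform(100.0, top, cfg.n_contaminant_peaks)
        cint = rng.lognormal(math.log(30.0), cfg.fragment_intensity_sigma,
                             cfg.n_contaminant_peaks)
        mz = np.concatenate([mz, cmz])
        intensity = np.concatenate([intensity, cint])
    return mz, intensity


def simulate_spectrum(
    p: Peptidoform,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    noisy: bool = False,
    identifier: str = "sim",
) -> Spectrum:
    """One fragment spectrum of ``p``: clean theoretical b/y peaks, optionally noised."""
    mz = _theoretical_peaks(p, cfg)
    intensity = _base_intensities(mz.size, cfg, rng)
    prec = precursor_mz(p)
    if noisy:
        mz, intensity = _perturb(mz, intensity, prec, cfg, rng)
    return Spectrum(
        identifier=identifier,
        precursor_mz=prec,
        precursor_charge=p.charge,
        mz=mz,
        intensity=intensity,
        provenance="experimental" if noisy else "synthetic",
    )


def simulate_spectrum_pair(
    p: Peptidoform,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    exp_id: str = "exp",
    syn_id: str = "syn",
) -> tuple[Spectrum, Spectrum]:
    """(noisy experimental-like, clean synthetic-like) twin spectra of ``p``.

    Both share one base intensity draw; only the noise parameters separate
    them, so at zero noise the pair is identical up to peak ordering.
    """
    mz = _theoretical_peaks(p, cfg)
    base = _base_intensities(mz.size, cfg, rng)
    prec = precursor_mz(p)
    clean = Spectrum(syn_id, prec, p.charge, mz, base, provenance="synthetic")
    nmz, nint = _perturb(mz, base, prec, cfg, rng)
    noisy = Spectrum(exp_id, prec, p.charge, nmz, nint, provenance="experimental")
    return noisy, clean


@dataclass
class ValidationSet:
    """Paired experimental-like / synthetic-like spectra with planted decoys."""

    experimental: list[Spectrum]
    synthetic: list[Spectrum]
    pairs: pd.DataFrame  # pair_id, experimental_id, synthetic_id, peptidoform, is_decoy
    ground_truth: GroundTruth

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "experimental_mgf": str(outdir / "experimental.mgf"),
            "synthetic_mgf": str(outdir / "synthetic.mgf"),
            "pairs_tsv": str(outdir / "pairs.tsv"),
            "ground_truth_json": str(outdir / "ground_truth.json"),
        }
        write_mgf(self.experimental, paths["experimental_mgf"])
        write_mgf(self.synthetic, paths["synthetic_mgf"])
        self.pairs.to_csv(paths["pairs_tsv"], sep="\t", index=False)
        self.ground_truth.to_json(paths["ground_truth_json"])
        return paths


def generate_validation_set(
    cfg: SimulationConfig,
    n_pairs: int,
    rng: np.random.Generator | None = None,
    candidates: Sequence[NitropeptideCandidate] | None = None,
) -> ValidationSet:
    """Build ``n_pairs`` spectrum pairs, a planted fraction of them decoys.

    True pairs share the base intensity draw between the noisy experimental
    spectrum and its clean synthetic twin; decoy pairs put the noisy spectrum
    of a *different* peptidoform against the synthetic one, emulating a wrong
    identification. The decoy count is ``round(n_pairs * decoy_fraction)``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if candidates is None:
        fasta = generate_proteome(cfg, rng)
        sites = assign_nitration_sites(fasta, cfg, rng)
        candidates = nitropeptide_candidates(fasta, sites, cfg)
        gt_sites = sites
    else:
        gt_sites = {}
    # distinct peptidoforms, stable order
    seen: dict[tuple[str, int], NitropeptideCandidate] = {}
    for c in candidates:
        seen.setdefault(c.key, c)
    pool = list(seen.values())
    if n_pairs > len(pool):
        raise InputError(
            f"n_pairs={n_pairs} exceeds available distinct nitropeptides ({len(pool)})"
        )
    chosen_idx = rng.choice(len(pool), size=n_pairs, replace=False)
    n_decoys = int(round(n_pairs * cfg.decoy_fraction))
    decoy_slots = set(
        rng.choice(n_pairs, size=n_decoys, replace=False).tolist() if n_decoys else []
    )

    experimental: list[Spectrum] = []
    synthetic: list[Spectrum] = []
    rows = []
    truth: dict[str, bool] = {}
    for slot, idx in enumerate(chosen_idx):
        cand = pool[int(idx)]
        p = cand.peptidoform(cfg.precursor_charge)
        pair_id = f"pair{slot + 1:04d}"
        exp_id, syn_id = f"exp.{pair_id}", f"syn.{pair_id}"
        if slot in decoy_slots:
            # wrong identification: noisy spectrum of another peptidoform
            other_idx = int(idx)
            while other_idx == int(idx):
                other_idx = int(rng.integers(len(pool)))
            other = pool[other_idx].peptidoform(cfg.precursor_charge)
            exp = simulate_spectrum(other, cfg, rng, noisy=True, identifier=exp_id)
            syn = simulate_spectrum(p, cfg, rng, noisy=False, identifier=syn_id)
            is_decoy = True
        else:
            exp, syn = simulate_spectrum_pair(p, cfg, rng, exp_id, syn_id)
            is_decoy = False
        experimental.append(exp)
        synthetic.append(syn)
        truth[pair_id] = is_decoy
        rows.append(
            {
                "pair_id": pair_id,
                "experimental_id": exp_id,
                "synthetic_id": syn_id,
                "peptidoform": p.proforma(),
                "is_decoy": is_decoy,
            }
        )
    return ValidationSet(
        experimental=experimental,
        synthetic=synthetic,
        pairs=pd.DataFrame(rows),
        ground_truth=GroundTruth(sites=gt_sites, pair_is_decoy=truth),
    )
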