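"""End-to-end orchestration: simulate or ingest, catalog, summarize, validate.

``run_full`` chains the stages — proteome/PSM simulation (or TSV/FASTA/MGF
ingest), site cataloging, N-terminal-fraction / overlap / motif summaries,
and spectral validation — writing every declared output plus a
machine-readable JSON run report whose per-stage counts reconcile
(emitted + rejected = input, per stage).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import (
    background_frequencies,
    build_catalog,
    catalog_frame,
    extract_windows,
    motif_matrix,
    n_terminal_fraction,
    overlap_summary,
    union_catalog,
)
from .masses import InputError
from .similarity import MatchParameters, compare_spectra, mirror_data, plot_mirror
from .simulate import (
    SimulationConfig,
    ValidationSet,
    assign_nitration_sites,
    generate_proteome,
    generate_validation_set,
    nitropeptide_candidates,
    simulate_capture,
)
from .spectra import Spectrum, write_fasta, write_psm_table

logger = logging.getLogger("nitroscope")

__all__ = ["RunReport", "run_validation", "run_full", "load_config"]


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    parameters: dict
    stage_counts: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def run_validation(
    pairs: pd.DataFrame,
    experimental: Mapping[str, Spectrum],
    synthetic: Mapping[str, Spectrum],
    params: MatchParameters = MatchParameters(),
    mirror_dir=None,
) -> tuple[pd.DataFrame, dict]:
    """Score every (experimental, synthetic) pair and summarize the pass fraction.

    ``pairs`` needs columns ``pair_id, experimental_id, synthetic_id``; the
    two mappings resolve spectrum identifiers. Returns the per-pair score
    table and a summary with the pass fraction at the score threshold.
    """
    rows = []
    for row in pairs.itertuples(index=False):
        exp = experimental.get(row.experimental_id)
        syn = synthetic.get(row.synthetic_id)
        if exp is None or syn is None:
            missing = row.experimental_id if exp is None else row.synthetic_id
            raise InputError(f"pair {row.pair_id!r}: spectrum {missing!r} not found")
        result = compare_spectra(exp, syn, params)
        rows.append(
            {
                "pair_id": row.pair_id,
                "score": result.score,
                "matched_peaks": result.alignment.matched_count,
                "alignment_slots": result.alignment.n,
                "passed": result.passed,
            }
        )
        if mirror_dir is not None:
            md = mirror_data(exp, syn, result)
            plot_mirror(md, title=str(row.pair_id),
                        path=Path(mirror_dir) / f"{row.pair_id}.png")
    table = pd.DataFrame(rows)
    n = len(table)
    n_passed = int(table["passed"].sum()) if n else 0
    summary = {
        "n_pairs": n,
        "n_passed": n_passed,
        "pass_fraction": (n_passed / n) if n else float("nan"),
        "threshold": params.similarity_threshold,
    }
    return table, summary


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - self.t0)
            return False

    return _T()


def run_full(
    cfg: SimulationConfig,
    outdir,
    params: MatchParameters = MatchParameters(),
    n_pairs: int = 100,
    motif_k: int = 7,
    write_mirrors: bool = False,
) -> RunReport:
    """Simulate a full study and run every analysis stage over it.

    Outputs under ``outdir``: proteome FASTA, per-mode PSM TSVs, catalog TSV,
    N-terminal-fraction TSV, overlap TSVs, motif count/frequency/log-odds
    TSVs, validation MGFs + pair table + per-pair scores TSV, ground-truth
    JSON, and ``run_report.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        parameters={
            "simulation": _jsonable(dataclasses.asdict(cfg)),
            "matching": dataclasses.asdict(params),
            "n_pairs": n_pairs,
            "motif_k": motif_k,
        }
    )
    outputs: dict[str, str] = {}

    with _timed("simulate"):
        rng = cfg.rng(0)
        fasta = generate_proteome(cfg, rng)
        sites = assign_nitration_sites(fasta, cfg, rng)
        candidates = nitropeptide_candidates(fasta, sites, cfg)
        psms = []
        for i, mode in enumerate(("protein_level", "peptide_level")):
            psms.extend(simulate_capture(candidates, cfg, mode, cfg.rng(1, i)))
        fasta_path = outdir / "proteome.fasta"
        write_fasta(fasta, fasta_path)
        outputs["proteome_fasta"] = str(fasta_path)
        for mode in ("protein_level", "peptide_level"):
            p = outdir / f"psms_{mode}.tsv"
            write_psm_table([r for r in psms if r.enrichment_mode == mode], p)
            outputs[f"psms_{mode}"] = str(p)
        report.stage_counts["simulate"] = {
            "proteins": len(fasta),
            "nitration_sites": sum(len(v) for v in sites.values()),
            "nitropeptide_candidates": len(candidates),
            "psm_rows": len(psms),
        }

    with _timed("catalog"):
        catalog, rejected = build_catalog(psms, fasta)
        frame = catalog_frame(catalog)
        cat_path = outdir / "catalog.tsv"
        frame.to_csv(cat_path, sep="\t", index=False)
        outputs["catalog"] = str(cat_path)
        report.stage_counts["catalog"] = {
            "input_psms": len(psms),
            "emitted_records": len(catalog),
            "rejected": len(rejected),
        }

    with _timed("sites"):
        nterm = n_terminal_fraction(catalog)
        p = outdir / "n_terminal_fraction.tsv"
        nterm.to_csv(p, sep="\t", index=False)
        outputs["n_terminal_fraction"] = str(p)

    with _timed("overlap"):
        for mode in ("protein_level", "peptide_level"):
            ov = overlap_summary(catalog, unit="protein", mode=mode)
            p = outdir / f"overlap_protein_{mode}.tsv"
            ov.to_frame().to_csv(p, sep="\t", index=False)
            outputs[f"overlap_{mode}"] = str(p)
        union = union_catalog(catalog)
        report.stage_counts["overlap"] = {"union": union}

    with _timed("motif"):
        windows = extract_windows(catalog, fasta, k=motif_k)
        bg = background_frequencies(fasta)
        mm = motif_matrix(windows, bg)
        for name, frame_ in (
            ("counts", mm.counts),
            ("frequencies", mm.frequencies),
            ("log_odds", mm.log_odds),
        ):
            p = outdir / f"motif_{name}.tsv"
            frame_.to_csv(p, sep="\t")
            outputs[f"motif_{name}"] = str(p)
        report.stage_counts["motif"] = {"windows": mm.n_windows}

    with _timed("validate"):
        vset = generate_validation_set(cfg, n_pairs, cfg.rng(2), candidates=candidates)
        paths = vset.write(outdir)
        outputs.update(paths)
        mirrors = outdir / "mirrors" if write_mirrors else None
        if mirrors is not None:
            mirrors.mkdir(exist_ok=True)
        table, summary = run_validation(
            vset.pairs,
            {s.identifier: s for s in vset.experimental},
            {s.identifier: s for s in vset.synthetic},
            params,
            mirror_dir=mirrors,
        )
        p = outdir / "validation_scores.tsv"
        table.to_csv(p, sep="\t", index=False)
        outputs["validation_scores"] = str(p)
        truth = vset.ground_truth.pair_is_decoy
        merged = table.assign(is_decoy=[truth[x] for x in table["pair_id"]])
        true_mask = ~merged["is_decoy"]
        summary.update(
            {
                "n_true_pairs": int(true_mask.sum()),
                "n_decoy_pairs": int((~true_mask).sum()),
                "sensitivity": float(merged.loc[true_mask, "passed"].mean())
                if true_mask.any()
                else float("nan"),
                "specificity": float((~merged.loc[~true_mask, "passed"]).mean())
                if (~true_mask).any()
                else float("nan"),
            }
        )
        report.validation = summary

    report.outputs = outputs
    report_path = outdir / "run_report.json"
    report.to_json(report_path)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_config(path) -> tuple[SimulationConfig, MatchParameters]:
    """Load a YAML config with optional ``simulation`` and ``matching`` sections."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    sim = data.get("simulation", {})
    if "antibodies" in sim:
        sim["antibodies"] = tuple(sim["antibodies"])
    if "peptide_length_bounds" in sim:
        sim["peptide_length_bounds"] = tuple(sim["peptide_length_bounds"])
    match = data.get("matching", {})
    return SimulationConfig(**sim), MatchParameters(**match)
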