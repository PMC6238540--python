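"""End-to-end orchestration: simulate/load -> filter -> fit -> call -> classify.

A run is driven by a :class:`RunConfig` (constructed in code, or loaded
from a YAML file with CLI flags overriding file values) and writes a run
directory containing the stage tables (TSV), a summary JSON and a log with
stage-level provenance (input hashes, seeds, package version).  The same
config and seed reproduce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import analyze_asa, classify_joint
from .decay import analyze_decay, permutation_fdr
from .filtering import filter_biased_snps
from .io import read_counts, write_counts
from .simulate import SimCohortConfig, simulate_cohort

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run (thresholds default to the
    published analysis: adjusted p < 0.05, |delta_lambda| > 0.06, twofold
    abundance divergence, 5,000 bootstrap lists, 100 permutations)."""

    counts: str | None = None            # existing counts TSV; None -> simulate
    bias_records: str | None = None      # optional bias-filter TSV
    simulate: dict = field(default_factory=dict)  # SimCohortConfig overrides
    n_boot: int = 5000
    n_perm: int = 100
    p_adj_threshold: float = 0.05
    min_abs_dlambda: float = 0.06
    min_abs_log2fc: float = 1.0
    min_snps: int = 5
    fdr_grid: tuple = tuple(round(0.01 * i, 2) for i in range(21))
    seed: int = 0

    def __post_init__(self):
        if self.p_adj_threshold <= 0 or self.min_abs_dlambda <= 0 \
                or self.min_abs_log2fc <= 0:
            raise ValueError("thresholds must be positive")
        if len(self.fdr_grid) == 0:
            raise ValueError("fdr_grid must be non-empty")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("asdecay")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        log.info("asdecay %s, seed %d", __version__, config.seed)

        if config.counts is None:
            sim = SimCohortConfig(**{"seed": config.seed, **config.simulate})
            counts, truths = simulate_cohort(sim)
            write_counts(counts, out / "counts.tsv")
            truth_df = pd.DataFrame([
                {"gene_id": t.gene_id, "N1_0": t.N1_0, "N2_0": t.N2_0,
                 "lambda1": t.lambda1, "lambda2": t.lambda2,
                 "delta_lambda_true": t.delta_lambda_true, "n_snps": t.n_snps}
                for t in truths])
            _write(truth_df, out / "truth.tsv")
            log.info("simulated cohort: %d genes", len(truths))
        else:
            counts = read_counts(config.counts)
            log.info("counts input %s sha256=%s", config.counts,
                     _sha256(Path(config.counts)))

        if config.bias_records is not None:
            records = pd.read_csv(config.bias_records, sep="\t")
            log.info("bias records input %s sha256=%s", config.bias_records,
                     _sha256(Path(config.bias_records)))
            retained, verdicts = filter_biased_snps(records,
                                                    alpha=config.p_adj_threshold)
            _write(verdicts, out / "bias_verdicts.tsv")
            tested = set(verdicts["snp_id"])
            keep = counts["snp_id"].isin(set(retained)) | ~counts["snp_id"].isin(tested)
            counts = counts[keep]
            log.info("bias filter: %d count rows retained", len(counts))

        results, asd_calls = analyze_decay(
            counts, n_boot=config.n_boot, seed=config.seed,
            p_adj_threshold=config.p_adj_threshold,
            min_abs_dlambda=config.min_abs_dlambda, min_snps=config.min_snps)
        if results.empty:
            raise ValueError("no gene passed the sufficiency filter")
        _write(results, out / "results.tsv")

        asa_results, asa_calls = analyze_asa(
            counts, n_boot=config.n_boot, seed=config.seed,
            p_adj_threshold=config.p_adj_threshold,
            min_abs_log2fc=config.min_abs_log2fc, min_snps=config.min_snps)
        _write(asa_results, out / "asa.tsv")

        _, decision_frame, class_summary = classify_joint(asd_calls, asa_calls)
        _write(decision_frame, out / "decisions.tsv")

        fdr = permutation_fdr(results, config.fdr_grid, n_perm=config.n_perm,
                              seed=config.seed,
                              p_adj_threshold=config.p_adj_threshold)
        _write(fdr, out / "fdr.tsv")
        at = fdr.loc[(fdr["threshold"] - config.min_abs_dlambda).abs().idxmin()]

        summary = {
            "version": __version__,
            "seed": config.seed,
            "n_boot": config.n_boot,
            "n_perm": config.n_perm,
            "thresholds": {"p_adj": config.p_adj_threshold,
                           "min_abs_dlambda": config.min_abs_dlambda,
                           "min_abs_log2fc": config.min_abs_log2fc},
            **class_summary,
            "compensatory_fraction": class_summary["frac_asd_without_asa"],
            "fdr_at_min_dlambda": None if pd.isna(at["fdr"]) else float(at["fdr"]),
            "complete": True,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     allow_nan=True) + "\n")
        log.info("run complete: %s", json.dumps(class_summary))
        return out
    except Exception:
        (out / "summary.json").unlink(missing_ok=True)
        (out / "INVALID").write_text("run failed; partial outputs are invalid\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


def summarize(run_dir) -> dict:
    """Load a completed run's summary and render a short text report."""
    run_dir = Path(run_dir)
    path = run_dir / "summary.json"
    if not path.exists() or (run_dir / "INVALID").exists():
        raise ValueError(f"{run_dir} does not contain a completed run")
    summary = json.loads(path.read_text())
    lines = [
        f"asdecay run ({run_dir})",
        f"  genes analyzed:        {summary['n_genes']}",
        f"  significant ASD:       {summary['n_asd']}",
        f"  significant ASA:       {summary['n_asa']}",
        f"  both:                  {summary['n_both']}",
        f"  ASD without ASA:       {_pct(summary['frac_asd_without_asa'])}",
        f"  ASA without ASD:       {_pct(summary['frac_asa_without_asd'])}",
        f"  perm. FDR at |dl| thr: {summary['fdr_at_min_dlambda']}",
    ]
    summary["report"] = "\n".join(lines)
    return summary


def _pct(x) -> str:
    return "NA" if x is None or pd.isna(x) else f"{100.0 * x:.1f}%"
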