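"""End-to-end pipeline: pileup → error model → edit calling → differential calls.

Stages are pure functions of their inputs plus the configuration, so a rerun
with the same inputs and configuration is bit-identical. Each run writes a
``run_info.json`` stamping every output with the configuration hash and the
package version; the hash covers exactly the statistically relevant
parameters, not paths or cosmetic settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .exceptions import ConfigError, InputError
from .io import (
    read_annotation,
    read_counts,
    read_design,
    read_fasta,
    write_json,
    write_table,
)
from .detection import (
    DEFAULT_PRIOR_EPSILON,
    call_editing_sites,
    two_pass_error_profiles,
)
from .differential import DIFF_COLUMNS, call_reduced_sites, compare_site_sets
from .pileup import pileup_base_tallies, pileup_counts
from .sites import SITE_KEY, scan_candidate_sites


@dataclass
class PipelineConfig:
    """Paths and statistical parameters for one analysis run."""

    design: str
    counts: str | None = None  # pre-computed counts table; skips the pileup stage
    reference: str | None = None  # FASTA, required with SAM input
    annotation: str | None = None  # transcript annotation TSV, required with SAM input
    sam: Mapping[str, str] = field(default_factory=dict)  # library_id → SAM path
    outdir: str = "orgedit_out"
    alpha_family_detection: float = 1e-3
    alpha_family_differential: float = 1e-3
    min_delta: float = 0.1
    pooling_mode: str = "pooled"
    min_libraries: int = 2
    prior_epsilon: float = DEFAULT_PRIOR_EPSILON
    fixed_epsilon: float | None = None  # bypass error estimation (counts-only input)
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_family_detection", "alpha_family_differential"):
            a = getattr(self, name)
            if not (0 < a < 1):
                raise ConfigError(f"{name} = {a} outside (0, 1)")
        if not (0 <= self.min_delta <= 1):
            raise ConfigError("min_delta must be in [0, 1]")
        if self.pooling_mode not in ("pooled", "per_replicate"):
            raise ConfigError(f"unknown pooling mode {self.pooling_mode!r}")
        if self.counts is None and not self.sam:
            raise ConfigError("provide either a counts table or SAM alignments")
        if self.sam and (self.reference is None or self.annotation is None):
            raise ConfigError("SAM input needs a reference FASTA and an annotation")

    def stat_params(self) -> dict:
        """The parameters that can change any statistical result."""
        return {
            "alpha_family_detection": self.alpha_family_detection,
            "alpha_family_differential": self.alpha_family_differential,
            "min_delta": self.min_delta,
            "pooling_mode": self.pooling_mode,
            "min_libraries": self.min_libraries,
            "prior_epsilon": self.prior_epsilon,
            "fixed_epsilon": self.fixed_epsilon,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.stat_params(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    counts: pd.DataFrame
    edit_calls: pd.DataFrame
    error_profiles: dict
    diff_calls: pd.DataFrame
    summary: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the result bundle to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = read_design(config.design)

    # --- stage: pileup (skipped when a counts table is supplied) ---
    tallies_by_lib: dict[str, pd.DataFrame] = {}
    if config.counts is not None:
        counts = read_counts(config.counts)
    else:
        try:
            reference = read_fasta(config.reference)
            annotation = read_annotation(config.annotation)
            sites = scan_candidate_sites(reference, annotation)
            frames = []
            for lib_id, sam_path in config.sam.items():
                frames.append(pileup_counts(sam_path, sites, reference, library_id=lib_id))
                tallies_by_lib[lib_id] = pileup_base_tallies(sam_path, reference, annotation)
            counts = pd.concat(frames, ignore_index=True)
        except (InputError, OSError) as exc:
            raise InputError(f"pileup stage failed: {exc}") from exc

    extra = set(counts["library_id"]) - set(design)
    if extra:
        raise InputError(f"counts contain libraries absent from design: {sorted(extra)}")

    # --- stage: error model ---
    if tallies_by_lib and config.fixed_epsilon is None:
        profiles = two_pass_error_profiles(
            tallies_by_lib,
            counts,
            prior_epsilon=config.prior_epsilon,
            alpha_family=config.alpha_family_detection,
        )
        epsilon = profiles
    else:
        profiles = {}
        epsilon = (
            config.fixed_epsilon if config.fixed_epsilon is not None else config.prior_epsilon
        )

    # --- stage: edit calling ---
    edit_calls = call_editing_sites(
        counts,
        epsilon,
        alpha_family=config.alpha_family_detection,
        min_libraries=config.min_libraries,
    )
    edited_keys = edit_calls.loc[edit_calls["site_edited"], SITE_KEY].drop_duplicates()

    # --- stage: differential calling over the edited-site universe ---
    edited_counts = counts.merge(edited_keys, on=SITE_KEY, how="inner")
    if not edited_counts.empty:
        diff_calls = call_reduced_sites(
            edited_counts,
            design,
            alpha_family=config.alpha_family_differential,
            min_delta=config.min_delta,
            mode=config.pooling_mode,
        )
    else:
        diff_calls = pd.DataFrame(columns=DIFF_COLUMNS)

    n_scanned = len(counts.drop_duplicates(subset=SITE_KEY))
    summary = summarize_run(diff_calls, n_scanned=n_scanned)

    # --- write bundle ---
    write_table(counts, outdir / "counts.tsv")
    write_table(edit_calls, outdir / "edit_calls.tsv")
    write_table(diff_calls, outdir / "diff_calls.tsv")
    if profiles:
        prof_rows = [
            {"library_id": lib, "substitution": sub, "rate": rate}
            for lib, prof in profiles.items()
            for sub, rate in sorted(prof.rate.items())
        ]
        write_table(pd.DataFrame(prof_rows), outdir / "error_profiles.tsv")
    write_json(
        {
            "config_hash": config.config_hash(),
            "orgedit_version": __version__,
            "parameters": config.stat_params(),
            "bonferroni": _bonferroni_log(diff_calls),
            "summary": summary,
        },
        outdir / "run_info.json",
    )
    (outdir / "summary.txt").write_text(render_summary(summary))
    return PipelineResult(config, counts, edit_calls, profiles, diff_calls, summary)


def _bonferroni_log(diff_calls: pd.DataFrame) -> dict:
    """Per-organelle divisor and threshold — the run's headline parameters."""
    if diff_calls.empty:
        return {}
    out = {}
    for org, sub in diff_calls.groupby("organelle"):
        out[org] = {"n_sites": int(len(sub)), "threshold": float(sub["threshold"].iloc[0])}
    return out


def _round_half_up_pct(num: int, den: int) -> int:
    import math

    return int(math.floor(100.0 * num / den + 0.5)) if den else 0


def summarize_run(diff_calls: pd.DataFrame, n_scanned: int | None = None) -> dict:
    """Per-organelle roll-up of the differential results."""
    per_org = {}
    for org, sub in diff_calls.groupby("organelle"):
        n = int(len(sub))
        n_sig = int(sub["significant"].sum())
        per_org[org] = {
            "n_edited_sites": n,
            "n_control_affected": int(sub["excluded_control_affected"].sum()),
            "n_significant": n_sig,
            "pct_affected": _round_half_up_pct(n_sig, n),
        }
    out = {"organelles": per_org}
    if n_scanned is not None:
        out["n_scanned_candidates"] = int(n_scanned)
    return out


def render_summary(summary: dict) -> str:
    lines = []
    if "n_scanned_candidates" in summary:
        lines.append(f"candidate C sites scanned: {summary['n_scanned_candidates']}")
    for org, s in sorted(summary.get("organelles", {}).items()):
        lines.append(
            f"{org}: {s['n_edited_sites']} edited sites, "
            f"{s['n_control_affected']} control-affected (excluded), "
            f"{s['n_significant']} significantly reduced "
            f"({s['pct_affected']}% of the edited universe)"
        )
    return "\n".join(lines) + "\n"


def summarize_overlap(diff_a: pd.DataFrame, diff_b: pd.DataFrame) -> dict:
    """Overlap of the significant site sets of two runs."""
    key = lambda df: set(map(tuple, df.loc[df["significant"], SITE_KEY].to_numpy()))
    a, b = key(diff_a), key(diff_b)
    inter, pct_a, pct_b = compare_site_sets(a, b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "n_shared": inter,
        "pct_of_a_shared": pct_a,
        "pct_of_b_shared": pct_b,
    }
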