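"""Synthetic STS-PCRseq experiments with known ground truth.

The generator emulates a virus-induced gene silencing (VIGS) experiment read
out by strand- and transcript-specific amplicon sequencing:

* organelle references (mitochondrion, plastid) carrying annotated transcripts
  with 5' leaders, and a chosen set of candidate C sites;
* true editing extents per site drawn from a truncated Beta law (most organelle
  sites are highly edited);
* three conditions — uninoculated control, GFP-silenced control (virus vector
  only) and treatment (factor-silenced) — with replicate libraries;
* virus-affected sites whose extent drops in BOTH inoculated conditions and
  silencing-affected sites whose extent drops only in the treatment;
* per-substitution sequencing error, near-uniform Poisson depth per site
  (equimolar amplicon pooling), and purely binomial replicate noise.

Count tables are multinomial draws per site and library; optionally the same
draws are realised as SAM alignments so the pileup stage can be exercised
end to end. Every output is a deterministic function of the configuration,
including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .io import COUNT_COLUMNS, CONDITIONS
from .sites import ANNOTATION_COLUMNS, COMPLEMENT, SITE_COLUMNS, scan_candidate_sites

SUBSTITUTIONS = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)

TRUTH_EXTENT_COLUMNS = {
    "uninoculated": "extent_uninoculated",
    "gfp_silenced": "extent_gfp_silenced",
    "treatment": "extent_treatment",
}

# distinct rng substreams per stage so stage outputs are individually reproducible
_STREAM_REFERENCE = 11
_STREAM_TRUTH = 13
_STREAM_COUNTS = 17
_STREAM_READS = 19


@dataclass(frozen=True)
class OrganelleSpec:
    """Size and planted-effect budget for one organelle genome."""

    name: str
    genome_length_bp: int
    n_candidate_sites: int
    n_edited_sites: int
    n_genes: int = 10
    n_virus_affected: int = 0
    n_silencing_affected: int = 0

    def validate(self) -> None:
        if self.genome_length_bp <= 0:
            raise ConfigError(f"{self.name}: genome length must be positive")
        if not (0 <= self.n_edited_sites <= self.n_candidate_sites):
            raise ConfigError(f"{self.name}: need 0 <= n_edited <= n_candidate")
        if self.n_genes < 1:
            raise ConfigError(f"{self.name}: need at least one gene")
        if self.n_virus_affected + self.n_silencing_affected > self.n_edited_sites:
            raise ConfigError(f"{self.name}: more planted effects than edited sites")


def default_error_rates(rate: float = 1e-3) -> dict[str, float]:
    """Uniform per-substitution error map (all 12 substitutions at ``rate``)."""
    return {s: rate for s in SUBSTITUTIONS}


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated silencing experiment.

    Defaults mirror the study design this package analyses: 8320 scanned C
    sites of which 618 mitochondrial and 38 plastid sites are truly edited,
    54 + 3 virus-affected sites, 35 silencing-affected mitochondrial sites,
    two biological replicates per condition, and ~1000x per-site depth from
    equimolar amplicon pooling.
    """

    seed: int = 0
    organelles: tuple[OrganelleSpec, ...] = (
        OrganelleSpec("mitochondrion", 40_000, 7000, 618, 30, 54, 35),
        OrganelleSpec("plastid", 9_000, 1320, 38, 10, 3, 0),
    )
    extent_beta: tuple[float, float] = (5.0, 2.0)
    extent_bounds: tuple[float, float] = (0.05, 1.0)
    error_rates: Mapping[str, float] = field(default_factory=default_error_rates)
    mean_depth: float = 1000.0
    depth_dispersion: float = 0.0  # 0 → Poisson depth; >0 → gamma-Poisson
    replicates: Mapping[str, int] = field(
        default_factory=lambda: {"uninoculated": 2, "gfp_silenced": 2, "treatment": 2}
    )
    delta_range: tuple[float, float] = (0.2, 0.5)
    read_length: int = 60

    def validate(self) -> None:
        for org in self.organelles:
            org.validate()
        if len({o.name for o in self.organelles}) != len(self.organelles):
            raise ConfigError("organelle names must be unique")
        a, b = self.extent_beta
        lo, hi = self.extent_bounds
        if a <= 0 or b <= 0:
            raise ConfigError("Beta parameters must be positive")
        if not (0 <= lo < hi <= 1):
            raise ConfigError("extent bounds must satisfy 0 <= lo < hi <= 1")
        for sub, rate in self.error_rates.items():
            if sub not in SUBSTITUTIONS:
                raise ConfigError(f"unknown substitution {sub!r}")
            if not (0 <= rate < 1):
                raise ConfigError(f"error rate {sub} = {rate} outside [0, 1)")
        if self.mean_depth <= 0:
            raise ConfigError("mean depth must be positive")
        if self.depth_dispersion < 0:
            raise ConfigError("depth dispersion must be >= 0")
        dlo, dhi = self.delta_range
        if not (0 < dlo <= dhi <= 1):
            raise ConfigError("planted deltas must lie in (0, 1]")
        for cond in CONDITIONS:
            if self.replicates.get(cond, 0) < 1:
                raise ConfigError(f"need at least one replicate for condition {cond!r}")
        if self.read_length < 1:
            raise ConfigError("read length must be >= 1")

    def libraries(self) -> list[tuple[str, str]]:
        """(library_id, condition) pairs, e.g. ('treatment_rep1', 'treatment')."""
        return [
            (f"{cond}_rep{r + 1}", cond)
            for cond in CONDITIONS
            for r in range(self.replicates[cond])
        ]

    def design(self) -> dict[str, str]:
        return dict(self.libraries())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["organelles"] = [asdict(o) for o in self.organelles]
        d["error_rates"] = dict(self.error_rates)
        d["replicates"] = dict(self.replicates)
        return d

    @classmethod
    def mito_universe(
        cls,
        seed: int = 0,
        n_sites: int = 618,
        mean_depth: float = 1000.0,
        n_virus: int = 0,
        n_silencing: int = 0,
        **overrides,
    ) -> "SimConfig":
        """An experiment over the mitochondrial edited-site universe only:
        every candidate site is truly edited, as when the differential stage
        runs on the called editing sites. With the defaults this is a null
        experiment (no planted effects)."""
        defaults = dict(
            seed=seed,
            organelles=(
                OrganelleSpec(
                    "mitochondrion", 20_000, n_sites, n_sites, 20, n_virus, n_silencing
                ),
            ),
            mean_depth=mean_depth,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "SimConfig":
        """A small experiment (one 10-gene organelle, modest depth) for fast
        end-to-end runs that include SAM emission."""
        defaults = dict(
            seed=seed,
            organelles=(OrganelleSpec("mitochondrion", 6_000, 150, 40, 10, 4, 6),),
            mean_depth=80.0,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# reference + annotation
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate organelle references, transcript annotations and candidate sites.

    Transcripts tile each genome with alternating strands and short intergenic
    gaps; ~10% of each transcript is a 5' leader, so candidate sites upstream
    of the start codon get negative labels. Candidate sites are a uniform
    draw (without replacement) from all sense-strand Cs of the annotation.

    Returns ``(reference, annotation, sites)``.
    """
    config.validate()
    rng = _rng(config, _STREAM_REFERENCE)
    reference: dict[str, str] = {}
    annot_rows = []
    site_frames = []
    bases = np.array(list("ACGT"))
    for org in config.organelles:
        seq = "".join(rng.choice(bases, size=org.genome_length_bp))
        reference[org.name] = seq
        block = org.genome_length_bp // org.n_genes
        gap = max(1, block // 20)
        if block - 2 * gap < 10:
            raise ConfigError(f"{org.name}: genome too short for {org.n_genes} genes")
        org_annot = []
        for g in range(org.n_genes):
            start = g * block + gap
            end = (g + 1) * block - gap
            strand = "+" if g % 2 == 0 else "-"
            leader = (end - start) // 10
            cds_start = start + leader if strand == "+" else end - 1 - leader
            org_annot.append(
                (f"{org.name[:2]}-gene{g + 1:02d}", org.name, start, end, strand, cds_start)
            )
        annot_rows.extend(org_annot)
        org_annot_df = pd.DataFrame(org_annot, columns=ANNOTATION_COLUMNS)
        all_sites = scan_candidate_sites({org.name: seq}, org_annot_df)
        if org.n_candidate_sites > len(all_sites):
            raise ConfigError(
                f"{org.name}: requested {org.n_candidate_sites} candidate sites "
                f"but only {len(all_sites)} sense-strand Cs are available"
            )
        chosen = np.sort(
            rng.choice(len(all_sites), size=org.n_candidate_sites, replace=False)
        )
        site_frames.append(all_sites.iloc[chosen])
    annotation = pd.DataFrame(annot_rows, columns=ANNOTATION_COLUMNS)
    if site_frames:
        sites = pd.concat(site_frames, ignore_index=True)
    else:
        sites = pd.DataFrame(columns=SITE_COLUMNS)
    return reference, annotation, sites


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _truncated_beta(rng, a, b, lo, hi, size):
    u = rng.uniform(stats.beta.cdf(lo, a, b), stats.beta.cdf(hi, a, b), size=size)
    return stats.beta.ppf(u, a, b)


def simulate_truth(sites: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign true editing states and per-condition extents to candidate sites.

    Per organelle, ``n_edited_sites`` candidates get a baseline extent from the
    truncated Beta law; the rest stay unedited (extent 0 everywhere). Among
    edited sites, virus-affected sites lose a planted delta in both inoculated
    conditions (GFP-silenced and treatment) and silencing-affected sites lose
    it in the treatment only, so virus artefacts are separable from genuine
    silencing effects by the dual-control comparison.
    """
    config.validate()
    rng = _rng(config, _STREAM_TRUTH)
    specs = {o.name: o for o in config.organelles}
    frames = []
    for org_name, org_sites in sites.groupby("organelle", sort=True):
        spec = specs[org_name]
        n = len(org_sites)
        truth = org_sites.reset_index(drop=True).copy()
        edited_idx = np.sort(rng.choice(n, size=spec.n_edited_sites, replace=False))
        baseline = np.zeros(n)
        a, b = config.extent_beta
        lo, hi = config.extent_bounds
        baseline[edited_idx] = _truncated_beta(rng, a, b, lo, hi, len(edited_idx))
        label = np.full(n, "unedited", dtype=object)
        label[edited_idx] = "stable"
        delta = np.zeros(n)
        n_affected = spec.n_virus_affected + spec.n_silencing_affected
        if n_affected:
            deltas = rng.uniform(*config.delta_range, size=n_affected)
            order = rng.permutation(edited_idx)
            taken: list[int] = []
            for d in deltas:
                pick = next((i for i in order if i not in taken and baseline[i] >= d), None)
                if pick is None:
                    raise ConfigError(
                        f"{org_name}: not enough edited sites with extent >= planted "
                        f"delta {d:.2f}; widen extent bounds or shrink delta_range"
                    )
                taken.append(pick)
            virus = taken[: spec.n_virus_affected]
            silenced = taken[spec.n_virus_affected :]
            label[virus] = "virus_affected"
            label[silenced] = "silencing_affected"
            delta[taken] = deltas
        truth["is_edited"] = baseline > 0
        truth["effect"] = label
        truth["true_delta"] = delta
        truth["extent_uninoculated"] = baseline
        truth["extent_gfp_silenced"] = np.where(
            label == "virus_affected", baseline - delta, baseline
        )
        truth["extent_treatment"] = np.where(
            np.isin(label, ["virus_affected", "silencing_affected"]),
            baseline - delta,
            baseline,
        )
        frames.append(truth)
    out = pd.concat(frames, ignore_index=True) if frames else sites.copy()
    return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _read_category_probs(p: np.ndarray, error_rates: Mapping[str, float]) -> np.ndarray:
    """(n, 3) probabilities that a read reports C, T or another base at a site
    with true extent ``p``, under the per-substitution error map.

    Errors apply symmetrically to edited (template T) and unedited (template C)
    molecules: an unedited molecule reads T with rate eps(C>T); an edited one
    reads C with rate eps(T>C).
    """
    e_ct = error_rates.get("C>T", 0.0)
    e_c_other = error_rates.get("C>A", 0.0) + error_rates.get("C>G", 0.0)
    e_tc = error_rates.get("T>C", 0.0)
    e_t_other = error_rates.get("T>A", 0.0) + error_rates.get("T>G", 0.0)
    p_t = p * (1 - e_tc - e_t_other) + (1 - p) * e_ct
    p_c = p * e_tc + (1 - p) * (1 - e_ct - e_c_other)
    p_other = np.clip(1.0 - p_t - p_c, 0.0, 1.0)
    probs = np.stack([p_c, p_t, p_other], axis=-1)
    return probs / probs.sum(axis=-1, keepdims=True)


def _draw_depths(rng, n: int, config: SimConfig) -> np.ndarray:
    if config.depth_dispersion > 0:
        shape = 1.0 / config.depth_dispersion
        lam = rng.gamma(shape, config.mean_depth / shape, size=n)
    else:
        lam = config.mean_depth
    return rng.poisson(lam, size=n)


def simulate_counts(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw per-library (nC, nT, nOther) tables from the ground truth.

    Depth at each site and library is Poisson around the configured mean
    (gamma-Poisson when ``depth_dispersion`` > 0); given depth, the three read
    categories are multinomial. Replicates of a condition share the same true
    extent and differ only by sampling noise.
    """
    config.validate()
    rng = _rng(config, _STREAM_COUNTS)
    n = len(truth)
    frames = []
    for lib_id, cond in config.libraries():
        p = truth[TRUTH_EXTENT_COLUMNS[cond]].to_numpy(dtype=float)
        depth = _draw_depths(rng, n, config)
        counts = rng.multinomial(depth, _read_category_probs(p, config.error_rates))
        lib = truth[SITE_COLUMNS].copy()
        lib["library_id"] = lib_id
        lib["nC"] = counts[:, 0]
        lib["nT"] = counts[:, 1]
        lib["nOther"] = counts[:, 2]
        frames.append(lib)
    if not frames:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _error_tables(error_rates: Mapping[str, float]):
    """Per-base total error rate and cumulative substitution weights."""
    tables = {}
    for b in "ACGT":
        targets = [t for t in "ACGT" if t != b]
        weights = np.array([error_rates.get(f"{b}>{t}", 0.0) for t in targets])
        tot = float(weights.sum())
        cum = np.cumsum(weights) / tot if tot > 0 else None
        tables[b] = (tot, targets, cum)
    max_tot = max(tables[b][0] for b in "ACGT")
    return tables, max_tot


def _apply_read_errors(sense: list[str], skip: int, rng, tables, max_tot) -> None:
    """Plant per-substitution sequencing errors at every position except ``skip``
    (the candidate site, whose base is already drawn from the site model)."""
    if max_tot <= 0:
        return
    u = rng.random(len(sense))
    for j in np.flatnonzero(u < max_tot):
        if j == skip:
            continue
        tot, targets, cum = tables[sense[j]]
        if tot <= 0 or u[j] >= tot:
            continue
        sense[j] = targets[int(np.searchsorted(cum, rng.random()))]


def simulate_alignments(
    truth: pd.DataFrame,
    config: SimConfig,
    reference: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Realise the simulated count tables as per-library SAM alignments.

    Each read covers exactly one candidate site (reads are clipped so they
    never span a neighbouring candidate), carries the site's drawn C/T/other
    base in transcript-strand orientation, and accrues per-substitution
    sequencing errors at its remaining positions. Reads from '-' strand
    transcripts are stored reverse-complemented with the reverse flag set, as
    a strand-specific protocol maps them. A pileup of the emitted SAM at the
    candidate sites therefore reproduces the count table exactly.

    Returns ``(counts, sam_text_by_library)`` where ``counts`` is the same
    table :func:`simulate_counts` produces for this truth and config.
    """
    counts = simulate_counts(truth, config)
    rng = _rng(config, _STREAM_READS)
    err_tables, max_tot = _error_tables(config.error_rates)
    sam_by_lib: dict[str, str] = {}

    # neighbour-exclusive windows per organelle
    windows: dict[tuple[str, int], tuple[int, int]] = {}
    for org_name, org_sites in truth.groupby("organelle"):
        pos = np.sort(org_sites["genomic_pos_0based"].to_numpy())
        length = len(reference[org_name])
        for i, p in enumerate(pos):
            lo = pos[i - 1] + 1 if i > 0 else 0
            hi = pos[i + 1] - 1 if i + 1 < len(pos) else length - 1
            windows[(org_name, int(p))] = (int(lo), int(hi))

    header_lines = ["@HD\tVN:1.6\tSO:unsorted"] + [
        f"@SQ\tSN:{name}\tLN:{len(seq)}" for name, seq in reference.items()
    ]

    for lib_id, _cond in config.libraries():
        lib_counts = counts[counts["library_id"] == lib_id]
        lines = list(header_lines) + [f"@RG\tID:{lib_id}"]
        for row in lib_counts.itertuples(index=False):
            org = row.organelle
            pos = int(row.genomic_pos_0based)
            lo, hi = windows[(org, pos)]
            n_other = int(row.nOther)
            site_bases = (
                ["C"] * int(row.nC)
                + ["T"] * int(row.nT)
                + list(rng.choice(["A", "G"], size=n_other))
            )
            seq = reference[org]
            for k, site_base in enumerate(site_bases):
                start = int(rng.integers(max(lo, pos - config.read_length + 1), pos + 1))
                end = min(start + config.read_length, hi + 1)
                fwd = seq[start:end]
                sense = list(fwd) if row.strand == "+" else list(_revcomp(fwd))
                i_sense = pos - start if row.strand == "+" else end - 1 - pos
                sense[i_sense] = site_base
                _apply_read_errors(sense, i_sense, rng, err_tables, max_tot)
                sense_str = "".join(sense)
                if row.strand == "+":
                    flag, seq_out = 0, sense_str
                else:
                    flag, seq_out = 16, _revcomp(sense_str)
                lines.append(
                    "\t".join(
                        [
                            f"{lib_id}:{org}:{pos}:{k}",
                            str(flag),
                            org,
                            str(start + 1),
                            "60",
                            f"{end - start}M",
                            "*",
                            "0",
                            "0",
                            seq_out,
                            "*",
                            f"RG:Z:{lib_id}",
                        ]
                    )
                )
        sam_by_lib[lib_id] = "\n".join(lines) + "\n"
    return counts, sam_by_lib


# ---------------------------------------------------------------------------
# one-call experiment bundle
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    """Everything one simulated experiment produced."""

    config: SimConfig
    reference: dict[str, str]
    annotation: pd.DataFrame
    sites: pd.DataFrame
    truth: pd.DataFrame
    counts: pd.DataFrame
    sam_by_library: dict[str, str] | None = None

    @property
    def design(self) -> dict[str, str]:
        return self.config.design()


def simulate_experiment(config: SimConfig, emit_sam: bool = False) -> Experiment:
    """Run the whole generator: reference → truth → counts (→ SAM)."""
    reference, annotation, sites = simulate_reference(config)
    truth = simulate_truth(sites, config)
    if emit_sam:
        counts, sam = simulate_alignments(truth, config, reference)
    else:
        counts, sam = simulate_counts(truth, config), None
    return Experiment(config, reference, annotation, sites, truth, counts, sam)
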