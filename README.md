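# orgedit

Detection and differential analysis of C-to-U RNA editing in plant organelle
transcripts, for experiments sequenced by strand- and transcript-specific
RT-PCR amplicon sequencing (STS-PCRseq-style designs).

In flowering-plant mitochondria and plastids, hundreds of cytidines in mRNAs
are post-transcriptionally converted to uridine; in cDNA reads an edited
position appears as T at a genomic C. `orgedit` is for groups that knock a
candidate editing factor down (e.g. by virus-induced gene silencing, VIGS) or
out, sequence organelle amplicons from treated and control plants, and need to
answer two questions: *which C positions are edited at all*, and *which edited
sites lose editing when the factor is removed*.

## The statistics at the core

**Editing-site detection.** At a candidate site, reads showing C or T are
modelled as Bernoulli with T-probability θ. With editing extent *p* and a
per-library empirical C→T sequencing error rate ε (estimated from genome-wide
mismatch tallies, excluding edited positions, with a 0.5 pseudocount),

θ = p + (1 − p)·ε,  H₀: θ = ε  vs  H₁: θ ∈ [ε, 1].

The likelihood-ratio statistic λ = 2[ℓ(θ̂) − ℓ(ε)], with
ℓ(θ) = n_T ln θ + n_C ln(1 − θ) and θ̂ = max(ε, n_T/(n_C + n_T)), is referred
to the boundary mixture ½χ²₀ + ½χ²₁ (the null sits on the edge of the
parameter space). The editing extent is estimated as
p̂ = (θ̂ − ε)/(1 − ε), and in practice as T/(C+T).

**Differential editing.** Replicate C and T counts are pooled per condition;
each site is tested by a Pearson χ² (1 df, no continuity correction) on the
2×2 table of pooled (n_C, n_T), treatment versus each control. Per organelle
the per-test threshold is the familywise rate α = 10⁻³ Bonferroni-divided by
the edited-site universe size (618 mitochondrial sites → P < 1.6×10⁻⁶; 38
plastid sites → P < 2.6×10⁻⁵), and a call additionally requires an absolute
extent reduction Δ ≥ 0.1. Because the silencing virus itself can depress
editing, sites already reduced in the GFP-silenced control versus uninoculated
plants are excluded, and a site is declared reduced only against **both**
controls.

A fully seeded synthetic-data module generates references, annotations, true
editing states, count tables and SAM alignments with planted silencing and
virus effects, so the entire pipeline is testable with known ground truth.

## Worked example

```sh
orgedit simulate --preset desk --seed 7 --outdir sim --emit-sam
orgedit diff-edit --counts sim/counts.tsv --design sim/design.tsv \
    --alpha-family 1e-3 --min-delta 0.1 --out diff.tsv
```

The desk preset simulates one 10-gene mitochondrial genome with 150 candidate
C sites, 40 of them edited, 4 virus-affected and 6 silencing-affected, at ~80×
depth. The second command prints:

```
mitochondrion: 150 edited sites, 3 control-affected (excluded), 6 significantly reduced (4% of the edited universe)
```

Three of the four planted virus artefacts reach significance in the
control-versus-control screen at this modest depth and are excluded (the
fourth is in any case blocked by the dual-control requirement), and exactly
the 6 sites whose editing was genuinely reduced by the silencing survive the
dual-control χ²/Bonferroni/Δ ≥ 0.1 procedure. (Here `diff-edit` was run on
all 150 candidate sites; `orgedit run` first restricts to LRT-called editing
sites.) The same analysis is available as a library:

```python
from orgedit import SimConfig, simulate_experiment, call_reduced_sites

exp = simulate_experiment(SimConfig.desk_scale(seed=7))
calls = call_reduced_sites(exp.counts, exp.design)
print(calls.loc[calls.significant, ["gene", "site_label", "delta_vs_uninoc"]])
```

```
          gene site_label  delta_vs_uninoc
12   mi-gene01       C413         0.267210
33   mi-gene03       C170         0.356557
93   mi-gene07        C10         0.396486
108  mi-gene08       C-41         0.278187
116  mi-gene08        C89         0.377717
125  mi-gene09       C269         0.267762
```

Each row is one significantly reduced site: the gene it sits in, its
gene-relative label (negative = 5′ leader, upstream of the start codon), and
the drop in editing extent relative to the pooled uninoculated controls.

The full pipeline (pileup from SAM → error calibration → LRT edit calls →
differential calls → report) runs from a JSON config via `orgedit run
--config cfg.json`; see `orgedit --help` for all subcommands.

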