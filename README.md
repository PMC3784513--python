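# mutmotif

Sequence-context analysis of single-base substitutions (SBSs) at G•C base
pairs. Most somatic mutations in cancer genomes and many pathogenic germline
mutations strike guanines, and how often a given guanine is hit depends
strongly on its neighbors. `mutmotif` classifies every substitution at a G•C
pair into one of the 64 canonical 5′-NGNN-3′ tetramer contexts — written on
the strand that carries the mutated guanine at position 2 (P2), with
mutations at a C folded onto the reverse strand by reverse complementation —
and provides the downstream statistics used to connect those context
preferences to the physical chemistry of DNA charge transfer: guanines in
low-ionization-energy stacks act as traps for migrating electron holes and
are mutated more often.

## What it computes

For motif *i* with *m_i* observed mutations (deduplicated by coordinate,
restricted to a mappability mask) and *t_i* mappable genomic occurrences:

- **Fractions** — *f_i* = *m_i*/*t_i* and subset-normalized
  *F_i* = *f_i*/∑*f_i* (∑*F_i* = 1 over the subset). Denominator counting
  doubles the four self-complementary tetramers (AGCT, CGCG, GGCC, TGCA),
  which carry two mutable guanines per double-stranded occurrence.
- **Group contrasts** — two-tailed Welch *t*-tests (or a pooled
  two-proportion *z*-test for sparse catalogs) between motif subsets:
  CGNN vs DGNN (D = A/G/T), DGRN vs DGYN (R purine, Y pyrimidine),
  DGAN vs DGBN (B = C/G/T); reported as −log10 P. Plus the P4-adenine
  ratio *f*(NGRA) / mean *f*(NGRB) that flags the melanoma-type hotspot.
- **Physicochemical correlates** — embedded vertical ionization potentials
  (VIPs, eV) for the 12 guanine-centered DGN trimers and a pluggable
  dinucleotide-step stacking table; log-linear fits ln *f* = a + b·x with
  *r*², two-tailed P and a bootstrap significance-persistence statistic
  P(α)₀.₀₅.
- **Recurrence enrichment** — coordinates hit in ≥2 samples, their motif
  enrichment *E_i* = (*d_i*/∑*d*)/(*t_i*/∑*t*) (≈1 under context
  independence), normalized tissue shares *S*, and GMT-based pathway hit
  ranking.
- **Transcription effects** — the per-motif non-transcribed/transcribed
  strand ratio *r* = NT/T, signed-position profiles of mutations around
  splice junctions (donor GT at +1,+2; acceptor AG at −2,−1; no position 0),
  and junction base-conservation matrices.
- **Spectrum clustering** — Manhattan distances between unit-sum context
  spectra, average-linkage trees, and bootstrap cluster support with a 0.90
  flagging threshold.
- **Synthetic data** — a fully seeded generator of genomes, mappability
  masks, gene models with canonical GT..AG introns, and context-biased
  multi-sample mutation catalogs (CpG/GpR/P4-A multipliers, VIP-log-linear
  rates, strand bias, recurrent-site injection), so every stage is testable
  with known ground truth.

## Worked example

```python
import mutmotif as mm

cfg = mm.SyntheticConfig(
    genome_length=300_000, n_genes=20, n_samples=12,
    mu=5e-4, kappa_cpg=5.0, kappa_gpr=2.0,
)
sim = mm.simulate_catalog(cfg, 2024)
ds = mm.deduplicate(mm.from_dataframe(sim["records"]))

m, excluded = mm.annotate_contexts(ds, sim["genome"], sim["mask"])
t = mm.count_genome_motifs(sim["genome"], sim["mask"])
ft = mm.normalize(mm.motif_fractions(m, t), "DGNN")

c = mm.compare_groups(ft, "CGNN", "DGNN")
print(f"CGNN vs DGNN ({c['test']}): mean f {c['mean_a']:.2e} vs "
      f"{c['mean_b']:.2e}, -log10 P = {c['minus_log10_p']:.1f}")
c2 = mm.compare_groups(ft, "DGRN", "DGYN")
print(f"DGRN vs DGYN ({c2['test']}): mean f {c2['mean_a']:.2e} vs "
      f"{c2['mean_b']:.2e}, -log10 P = {c2['minus_log10_p']:.1f}")
```

prints

```
CGNN vs DGNN (welch_t): mean f 2.88e-02 vs 9.07e-03, -log10 P = 10.8
DGRN vs DGYN (welch_t): mean f 1.22e-02 vs 5.97e-03, -log10 P = 11.6
```

The injected CpG hotspot (κ_CpG = 5) appears as a ~3-fold mean-fraction
excess of CGNN over DGNN motifs (the DGNN mean itself is inflated by the
κ_GpR = 2 purine effect), and the κ_GpR = 2 injection is recovered as the
~2-fold DGRN/DGYN excess; both contrasts are decisively significant at this
catalog size (1,438 deduplicated substitutions).

A CLI mirrors the main steps:

```sh
mutmotif simulate --seed 5 --length 200000 --prefix sim
mutmotif count --fasta sim.fa --mask sim.mask.bed --out counts.tsv
mutmotif fractions --fasta sim.fa --mutations sim.mutations.tsv \
    --mask sim.mask.bed --counts counts.tsv --out fractions.tsv
mutmotif contrast --fractions fractions.tsv --groups CGNN:DGNN
```

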