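# Methods

## The model

The tRNA adaptation index (tAI) treats translation elongation as limited by
the supply of decoding tRNA. For each sense codon *i* the absolute
adaptiveness is

    W_i = sum_j (1 − S_ij) · tGCN_ij

where the sum runs over the anticodons *j* able to recognize codon *i*,
tGCN_ij is the genomic gene copy number of anticodon *j* (a standard proxy
for tRNA abundance), and S_ij ∈ [0, 1] is the coupling-efficiency penalty of
the codon–anticodon interaction class (0 = perfect pairing, 1 = no effective
decoding). Relative adaptiveness is w_i = W_i / max_i W_i, and the tAI of a
gene is the geometric mean of the w of its codons.

Recognition follows third-position wobble rules, with anticodons written
5'→3' in DNA so the wobble base (position 34) is the first character and the
Watson–Crick (WC) anticodon of a codon is its reverse complement. For a
codon ending in U the recognizers are the A34 anticodon (WC) and the G34
variant (G:U class); ending in C — G34 (WC) and A34 (inosine reading C,
I:C); ending in A — U34 (WC) and A34 (I:A); ending in G — C34 (WC) and U34
(U:G). Met ATG and Trp TGG are restricted to their WC anticodons so that
initiator-tRNA copies are not credited as wobble capacity; stop codons are
excluded everywhere. In prokaryote mode the bacterial Ile2 tRNA (CAT
anticodon with lysidine-modified C34) additionally decodes ATA (class L:A);
its copy number is carried separately from Met CAT so the two are never
conflated.

WC penalties are pinned at 0; the free parameters are the wobble classes
{G:U, I:C, I:A, U:G} plus L:A in prokaryote mode. Codons with W = 0 (no
decoding tRNA gene) receive a w imputed as the geometric mean of the
non-zero w values so the tAI logarithm stays defined; they are flagged in
`AdaptivenessMap.zero_substituted`. A fixed literature vector (G:U 0.41,
I:C 0.28, I:A 0.9999, U:G 0.68, L:A 0.89) ships as the `OTAI_SIJ` preset for
scoring without inference; these are external constants, not values fitted
here.

## Species-specific inference of S_ij

The inference requires no expression data. Steps:

1. **Reference set.** Gene-level codon usage bias is measured with the
   improved effective number of codons,
   ENc = Ns + Σ_m K_m · (Σ_j n_j)/(Σ_j n_j F_CF,j), where
   F_CF = Σ_i ((n_i+1)/(n+m))² is the pseudocounted family homozygosity.
   Under the split standard code (six-fold Leu/Ser/Arg divided into 2- and
   4-fold blocks by their first two nucleotides) Ns=2, K2=12, K3=1, K4=8,
   giving the conventional ceiling of 61. The lowest-ENc fraction of the
   genome (default 5%, floor of 5 genes) is taken as the putatively highly
   expressed reference set.
2. **Reference RSCU.** Relative synonymous codon usage,
   RSCU_c = O_c / ((1/k_a)·Σ O), on the *pooled* codon counts of the
   reference genes; families with zero counts are undefined and excluded.
3. **Optimization.** A genetic algorithm searches the free S vector to
   maximize the Spearman rank correlation, at the codon level, between the
   reference RSCU and W_i. Chromosomes are real vectors in [0,1]^k;
   the loop uses tournament selection (k=2), uniform crossover (p=0.8),
   per-gene Gaussian mutation (sd 0.1, rate 0.1) clipped to bounds, and one
   elite, for 100 generations with population 60 by default. The trace of
   best-so-far fitness is monotone by construction and runs are
   bit-reproducible under a seed. The operator suite is a standard
   real-valued GA configuration; all pieces are configurable.
4. **Scoring.** The best S vector yields W, w and per-gene tAI.

The codon set entering the fitness is the sense codons of multi-codon
families with defined reference RSCU (single-codon families carry constant
RSCU and no rank information). Candidates producing a constant W vector
score −inf rather than aborting a run; construction-time degeneracies
(fewer than 3 usable codons, constant RSCU) raise immediately.

## Comparator indices and evaluation statistics

CAI uses Sharp–Li reference weights (within-family count / max count,
pseudocount 0.5 for unobserved codons) and geometric-mean scoring over
multi-codon families. SCUO is the entropy-based orderliness index:
per family O_i = (log2 m_i − H_i)/log2 m_i, weighted by the family's share
of counts; reference-free, in [0,1]. GC content is reported as the
arithmetic mean of per-gene percentages (a pooled-nucleotide mode is
available by flag).

Two indices' correlations with a shared third variable are compared with
Williams' t for dependent correlations,

    t = (r12 − r13) · sqrt( (n−1)(1+r23) /
          ( 2K(n−1)/(n−3) + r̄²(1−r23)³ ) ),  df = n − 3,

with K the determinant of the 3×3 correlation matrix and r̄ = (r12+r13)/2;
two-sided p from the t distribution. Repeated-subsample correlation draws
25% of the paired values with replacement (1000 replicates by default) and
records each replicate's Spearman rho; degenerate replicates are kept as
missing with a warning rather than redrawn, so replicate counts stay
honest.

## The synthetic-genome generator

The generator instantiates exactly the assumption the inference exploits,
nothing more. Given a tRNA pool and a true S vector, it computes the true w
and emits two gene classes: highly expressed genes draw amino acids
uniformly and pick each codon with probability ∝ w_true^β (a Boltzmann tilt
with selection strength β), and background genes pick codons by a neutral
per-nucleotide GC weight (gc_bias, default 0.5 = unbiased). Every gene
starts with ATG, ends with a stop, and contains no internal stops, so the
output passes strict CDS validation by construction. Defaults are 200 high
+ 1800 background genes (a 10% highly expressed tier), lengths uniform in
100–400 codons, β = 5, and the literature S vector as truth. The default
tRNA pool includes each WC anticodon with probability 0.7 and 1–10 gene
copies, repairing any undecodable amino-acid family; user-supplied pools
that leave a family undecodable are rejected.

What the generator does *not* emulate: expression-level gradients (the
"high" tier is homogeneous), amino-acid composition bias, GC-content
covariation with selection, operon or strand structure, or any evolutionary
dynamics. Passing tests therefore demonstrate correctness of the machinery
and behaviour of the objective under its own idealized premise — not
accuracy on real genomes.

## What the objective can and cannot recover

A finding worth stating plainly: even under the idealized generative model,
the RSCU-vs-W rank objective is a **biased** estimator of S_ij. RSCU
normalizes within families (factor k_a / Σ_family counts), which inflates
the top codons of families whose synonymous alternatives are weakly decoded
relative to families with several well-decoded codons. The global optimum
of the fitness therefore sits at systematically larger S than the
generating truth (observed: fitness ≈ 0.70–0.78 at the optimum vs
0.63–0.71 at the truth; recovered free S biased upward by up to ~0.6;
Spearman(w_true, w_est) ≈ 0.69–0.88). The optimizer itself is sound — it
matches or beats an exhaustive grid on low-dimensional instances — and the
resulting tAI still ranks selected genes far above background and
correlates with CAI only when selection is present. Users should read the
inferred S values as effective rank-fitting parameters, not as physical
pairing efficiencies.

## Numerical and design choices

- **CDS filters** (defaults): ≥ 30 codons, ≤ 5% ambiguous bases, no
  internal stops; chosen to keep per-gene codon statistics meaningful on
  fragments. Codons containing N are skipped, never attributed.
- **ENc empty-fold fallback**: if every family of a fold class has zero
  counts (possible for the single 3-fold Ile family in short genes) its
  term is the uniform-usage limit K_m·m, preserving the 61 ceiling.
- **Reference fraction** 0.05 with a floor of 5 genes; ties at the ENc cut
  break by input order, making selection deterministic.
- **Spearman ties** use average ranks throughout; the GA's internal
  correlation is a vectorized rank-then-Pearson equal to scipy's
  `spearmanr` to 1e-12 (tested).
- **Seeding**: all randomness flows through `numpy.random.default_rng`
  seeds carried in configs and echoed in run reports; identical seed +
  config ⇒ byte-identical output files.
- **Problem sizes** used by the test suite and the acceptance script: the
  main study condition is the generator default (2000 genes); optimizer
  robustness sweeps (population sizes 10–100 × 5 seeds, and 1000-generation
  traces) run on a 300-gene genome with 60–150-codon genes, which leaves
  the measured quantities unchanged while keeping full sweeps cheap.

## Known limitations

- Wobble rules are written for the standard nuclear/bacterial codes
  (NCBI tables 1 and 11); other tables get correct family partitions but
  the recognizer table assumes standard decoding.
- tGCN is a proxy; no tRNA modification or charging information enters.
- The reference set is a heuristic for "highly expressed"; genomes with
  weak overall codon bias (high genome-wide ENc) give flat RSCU signals and
  low optimizer fitness, and the inferred S is then poorly constrained.
- S_ij values are effective parameters (see above), comparable across runs
  of this package but not directly interpretable as biophysical constants.
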