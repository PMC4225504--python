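# phylokit

Fast distance-based phylogenetics for large alignments: estimate pairwise
evolutionary distance matrices from DNA or protein alignments, and
reconstruct unrooted phylogenies from them with neighbor joining (NJ), fast
neighbor joining (FNJ), or BioNJ. The package is aimed at pipelines that
need distance trees at scale — guide trees for alignment or ML searches,
quick gene-family phylogenies, bootstrap batches — where the distance
matrix, not the tree search, is the real bottleneck: for n sequences of
length ℓ the matrix costs O(ℓn²) before any tree is built.

Everything is exposed both as a Python library and as pipe-composable
command-line tools (`dnadist`, `protdist`, `treebuild`, `synth`) that read
FASTA/PHYLIP/XML and write PHYLIP, a validatable XML dialect, Newick, and a
compact streaming binary matrix format.

## The methods

**DNA distances.** From each aligned pair the tool tallies the proportion
of sites that match, differ by a transition (A↔G with proportion P₁, C↔T
with P₂; P = P₁+P₂), or differ by a transversion (Q), with pairwise deletion
of gapped sites. Four estimators map these to expected substitutions per
site:

- p-distance: d = p (the raw difference proportion);
- Jukes–Cantor: d = −(3/4)·ln(1 − 4p/3);
- Kimura 2-parameter (default): d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q);
- Tamura–Nei 1993, which additionally uses the base composition
  π̂ estimated from the pair.

IUPAC ambiguity codes are not discarded: a site pairing symbols with
candidate sets S_a, S_b contributes weight 1/(|S_a||S_b|) to the category of
each (x, y) ∈ S_a×S_b, so every comparable site still carries unit weight.

**Protein distances.** Besides two correction formulas (a 20-state
Jukes–Cantor analogue and Kimura's PAM approximation), five empirical
replacement models are bundled — WAG, JTT, Dayhoff, MVR (the VT matrix),
and LG. For a model with reversible generator Q (scaled to one expected
substitution per site per unit distance) the two-sequence likelihood is
Pr(a,b|d) = Π_sites π(aᵢ)·[e^{Qd}]_{aᵢbᵢ}. The maximum-likelihood distance
argmax_d Pr(a,b|d) is found by Newton–Raphson with analytic derivatives
from the spectral decomposition of Q; the posterior-expected distance
E[d|a,b] integrates over a flat prior on a geometric grid.

**Tree building.** All methods minimize the NJ selection criterion
S(i,j) = (m−2)·D(i,j) − R(i) − R(j) with R(i) = Σ_k D(i,k). Canonical NJ
scans all pairs each step (O(n³) total). FNJ keeps a *visibility set* — one
stored candidate partner per node — and joins the best visible pair,
reducing total selection work to O(n²). BioNJ selects like NJ but reduces
the matrix with a variance-weighted mixture λ ∈ [0,1]. On an additive
(tree) metric all three reconstruct the generating tree exactly, branch
lengths included.

**Bootstrap.** Column resampling is built into both distance tools
(`-b B`, `-k` to drop the original-data matrix, `-s SEED`); replicate r is
reproducible from (seed, r) alone, so replicates can run as independent
jobs.

**Binary matrix format.** The upper triangle (diagonal excluded) is stored
as little-endian float32 behind a small header (`FPB1`, version, count,
length-prefixed UTF-8 identifiers): exactly header + 4·n(n−1)/2 bytes,
written and read strictly row-by-row so only one matrix row is ever held in
memory. For 100,000 taxa that is ≈18.6 binary GB, versus roughly 9·n²
bytes (≈84 GB) as square PHYLIP text with six printed decimals.

## Worked example

Generate a 6-taxon synthetic family (K2P model, 1000 sites), estimate
distances, and build a tree:

```sh
phylokit synth -n 6 -l 1000 --model k2p -s 11 -o ex.fasta --tree-out ex_true.nwk
phylokit dnadist ex.fasta          # K2P matrix, PHYLIP square layout
phylokit dnadist ex.fasta | phylokit treebuild -m fnj
```

The matrix (entries are expected substitutions per site; e.g. t2–t5 are
nearly identical at 0.012, while t4 is the most divergent taxon):

```
6
t3  0.000000 0.132154 0.397097 0.098408 0.124109 0.130142
t1  0.132154 0.000000 0.470457 0.217404 0.235209 0.235130
t4  0.397097 0.470457 0.000000 0.480874 0.500761 0.506450
t6  0.098408 0.217404 0.480874 0.000000 0.053988 0.060484
t2  0.124109 0.235209 0.500761 0.053988 0.000000 0.012098
t5  0.130142 0.235130 0.506450 0.060484 0.012098 0.000000
```

and the FNJ tree:

```
(t3:0.0116584,(t1:0.112241,t4:0.379086):0.0291927,(t6:0.0188694,(t2:0.0045797,t5:0.00714069):0.0346059):0.0703781);
```

which recovers the generating topology in `ex_true.nwk` — t2+t5 as the
tightest cherry, then t6, t3, and the long t4 branch — with branch-length
estimates within sampling error of the true values.

The same flow works for proteins (`phylokit protdist aln.fasta -m lg
--method ml`) and with the binary format over a pipe
(`phylokit dnadist aln.fasta -O binary | phylokit treebuild -I binary`).

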