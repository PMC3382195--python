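# Methods

`pbscope` analyses local structural divergence among homologous protein
domains through the Protein Block (PB) structural alphabet.  This note
documents the models, the constants, the synthetic data the pipeline is
exercised on, and the numerical choices, in the order the pipeline runs.

## The Protein Block alphabet

A PB is one of 16 pentapeptide backbone prototypes labelled `a`–`p`, each
defined by 8 consecutive dihedral angles

    (psi_{i-2}, phi_{i-1}, psi_{i-1}, phi_i, psi_i, phi_{i+1}, psi_{i+1}, phi_{i+2}).

`m` and `d` are the central α-helix and β-strand prototypes; `a`–`c` mark
strand N-caps, `e`–`f` strand C-caps, `k`/`l` helix N-caps, `n`–`p` helix
C-caps, and `g`–`j` coils and turns.  A backbone is encoded one residue at a
time: measure the residue's 8-angle window and assign the prototype with
minimal RMSDA (root-mean-square deviation over angles with circular
differences, `min(|Δ|, 360−|Δ|)`).  Windows that are incomplete — the first
and last two residues of every chain, residues near a chain break
(C–N distance > 2.0 Å or non-consecutive numbering), residues with missing
backbone atoms — are encoded `Z` and excluded from every statistic.

The shipped prototype table (`pbscope/data/pb_prototypes.txt`) is the
canonical 16×8 reference angle set with the central (φ, ψ) pairs fixed to
the printed reference values this package treats as authoritative for 13 of
the 16 PBs; `e`, `g`, `l` keep canonical values throughout.  Two of the
printed centres differ from the older canonical table — `j`'s ψ is +150.05°
and `p`'s centre is (59.85°, 21.51°), an α_L-type conformation consistent
with the Schellman-motif geometry of the `p`–`a` helix C-cap — and the
printed values win by design.  Ties in assignment (RMSDA within 1e-9°)
resolve to the alphabetically first label.  Torsions follow the IUPAC sign
convention and live in (−180°, 180°]; degenerate geometry (collinear bonds)
raises an error rather than returning NaN.

## Substitution statistics

Input is a set of pairwise structural alignments of homologous domains,
each carrying both PB strings, per-column Cα distances after superposition,
a family id, a SCOP class label, sequence identity and optionally
resolution.  The estimation pipeline:

1. **Filter** — keep pairs with identity strictly below 40% (80% for the
   indel survey) and, when resolution is known, better than 2 Å.
2. **Count** — for every aligned column with both PBs ≠ `Z` and Cα distance
   ≤ 3 Å (the *conserved core*; "within" is inclusive), increment
   N[i, j].  Counts accumulate per family.
3. **Normalize by family** — divide each family's count matrix by its
   number of pairs before pooling, so a 100-pair family and a 1-pair family
   carry equal per-pair weight.  Pooled counts are invariant to duplicating
   pairs within a family.
4. **Log-odds** — symmetrize (N'ᵢⱼ = Nᵢⱼ + Nⱼᵢ; N'ᵢᵢ = 2Nᵢᵢ), add a
   pseudocount (+1 per cell by default; keeps every score finite even for
   classes with sparse substitution information), form ordered-pair
   frequencies q = N'/ΣN' and marginals pᵢ = Σⱼ qᵢⱼ, and score

       S_ij = log2( q_ij / (p_i p_j) ).

   On ordered-pair-normalized frequencies the factor-2 expected-frequency
   correction of the unordered-pair convention cancels, so this is the
   standard symmetric observed-over-expected weight: uniform counts give
   all-zero scores, diagonal concentration gives positive diagonal scores.
   Log base and scale are configurable.

Class-specific matrices run the same pipeline on each SCOP class's pairs.
Matrices are compared row-wise by Pearson correlation (all 16 entries,
diagonal included); rows with r < 0.95 are inspected for outlier cells with
the 1.5·IQR rule on absolute score differences (type-7 linear-interpolation
quartiles; a zero IQR degenerates to flagging values different from the
median).  PBs are clustered on the distance 1 − r between score rows with
complete-linkage agglomeration (scipy); dendrograms export as Newick.

## PB-based alignment and superposition

Structures are aligned by Smith–Waterman local dynamic programming over
their PB strings under a substitution matrix with a linear gap penalty of
−5.0 per gap position (a single penalty; an open/extend distinction is
deliberately absent).  `Z` scores 0 against everything so termini never
drive the local optimum.  The traceback is deterministic (ties: diagonal >
up > left; the end cell is the first maximal cell in row-major order) and
the reported score is exactly recomputable from the emitted gapped strings.
The aligned Cα pairs are then superposed by the SVD-based Kabsch solution
(proper rotations only; `scipy.spatial.transform.Rotation.align_vectors`)
and the fit rmsd is the quality measure.  Matrix benchmarking aligns each
test pair under a candidate and a reference matrix and classifies the pair
better/same/worse by fit rmsd with a 0.01 Å tie tolerance.

## Accessibility strata

Relative solvent accessibility (RSA, % of a fully exposed reference
maximum) comes from NACCESS-style `.rsa` tables or from an internal
Shrake–Rupley calculation (Bio.PDB; 960 sphere points, 1.4 Å probe,
Chothia-type element radii, Tien et al. theoretical reference maxima —
absolute values differ slightly from NACCESS output).  A residue is
*accessible* when RSA is strictly above the cutoff (7, 15 or 25%); a PB
position is *exposed* when at least 3 of the 5 residues of its window are
accessible, else buried.  Doubling the alphabet to 32 labels (`m_e`, `m_b`,
…) and re-running the counting pipeline yields the stratified matrix
(default cutoff 25%); marginalizing its 2×2 stratum blocks reproduces the
plain 16×16 counts exactly, which the tests assert.

## Indel hotspots

A maximal gap run of length n in either row of an alignment (pairs below
80% identity) is an indel site when the 3 columns immediately on each side
are aligned pairs within 3 Å.  The site is labelled by the di-PB — the two
PB symbols of the *un-inserted* sequence bounding the gap, read N→C — and a
6-symbol context (2 PBs each side of the di-PB); any `Z` in the context
rejects the site.  Insert lengths pool into classes 1, 2, 3, 4, 5+.  Per
class with T sites, each di-PB d with background frequency p_d (the
frequency of consecutive non-Z ordered pairs over the whole dataset) is
scored with the one-sample binomial-proportion statistic

    Z_d = (O_d − T·p_d) / sqrt(T·p_d·(1 − p_d)),

preferred when Z > 2.  The source protocol specifies only "deviation from
the expected distribution"; the binomial-proportion form is this package's
choice and is recorded in the report metadata.  Degenerate backgrounds
(p_d ∈ {0, 1}) yield an explicit undefined-Z flag.  The modal 6-PB context
of each hotspot is reported with its percentage among that di-PB's sites.

## Synthetic homolog families

All inputs are generated, never downloaded.

**Backbones.** N/CA/C chains are built by sequential internal-coordinate
placement (NeRF) with ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°; ω = 180°),
writing each position's (φ, ψ) as its PB's central angles.  The
construction/measurement round trip is exact to ≪ 0.01°.

**Realized vs intended strings.** Each PB constrains an overlapping
5-residue window but the builder writes only central angles, so the encoder
may re-label positions, especially next to substitutions.  Family templates
are therefore *realization-stable* strings — random strings iterated
through the encoder to a fixed point (convergence within a few rounds) —
which the encoder reproduces exactly, like real PB sequences, which are
consistent with their own backbone by construction.  The truth bundle
records both intended and realized strings; recovery tests compare against
realized truth.

**Homolog pairs.** From a family template: substitutions are drawn
per position (default rate 0.2, realistic for homolog pairs below 40%
identity) from a class-specific replacement process (baseline: P(y|x) ∝
exp(−RMSDA(x, y)/30°), so conformationally similar PBs interchange more);
insertions are planted at chosen di-PB contexts of the realized template;
torsions get Gaussian noise (default σ 3°, flipping ~0.5% of labels);
coordinates are rebuilt and optionally jittered; amino acids are mutated
independently of the PBs to hit a target identity (default 15–35%).

**Per-column distances.** A single global rigid fit of extended NeRF chains
would let any torsion change propagate to every downstream residue —
synthetic chains lack the compact-fold tethering that lets real domains
absorb local changes.  Distances are therefore measured after a rigid fit
of a sliding window of 11 aligned pairs centred on each column, with
windows never bridging a gap run (the rigid core on either side of a loop
excursion superposes independently).  Under this measure ~85% of aligned
columns fall within 3 Å at the default noise/rate, ≥ 99% under pure 0.5 Å
coordinate jitter, and large conformational flips (e.g. helix→strand at one
position) correctly exceed 3 Å and leave the conserved core.

**What passing means.** The generator emulates conserved cores, controlled
substitution processes, planted indels, family-size imbalance and class
labels — not real fold topology, side chains, packing or co-evolution.
Recovery results demonstrate that the estimation machinery is unbiased and
sensitive under known truth; they do not certify the biological conclusions
that real structural datasets would support.  Backbone-only chains are also
systematically more solvent-exposed than real packed domains, so synthetic
exposure ratios are uniformly high at low cutoffs; the burial machinery is
validated by construction-based fixtures instead.

## The two-class recovery study

The headline integration test plants a class difference and asks the
pipeline to find it: 2 classes × 20 families (sizes cycling 4, 8, 12, 16;
500-residue templates; ~10⁵ aligned columns per class) share the baseline
process except that PB `p`'s substitution flux is fully redirected — to `m`
in one class, to `j` in the other.  The redirect pair was chosen by an
angle-space design analysis of which substitutions the encoder can realize
*visibly* (off-diagonal and inside the 3 Å core): most nominal
substitutions either realize back to the template label or move the
backbone out of the core, exactly as large conformational changes are
excluded in the real protocol.  Estimated per-class matrices recover the
realized truth ordering with Spearman ρ ≈ 0.98–0.99 (off-diagonal cells, vs
the pooled truth tally), and row-wise comparison of the two class matrices
flags the same rows (r < 0.95) as the truth bundle's family-normalized
tally — the set {b, c, p} under these conditions, always containing the
redirected source `p`.  The Spearman check deliberately uses the
*unnormalized* truth tally (different family weighting than the estimator)
so it is not a self-comparison; the flag-set check uses the
family-normalized tally so borderline rows cannot flip for weighting
reasons alone.

The indel study plants insertions only at di-PBs (p, a) and (h, i) (20
families, 300-residue templates, lengths 1–8 skewed short).  The flank rule
recovers ~35% of planted sites (substitution noise pushes the rest past
3 Å); every populated length class flags exactly the planted di-PBs at
Z ≫ 2 with zero false flags against a ≥ 50× larger background.

## Numerical and interface choices

- Angles: degrees, (−180°, 180°], 2-decimal printing, full precision
  internally.
- Strict "<" for identity and resolution cutoffs; "≤" for the 3 Å core
  rule; strict ">" for RSA-above-cutoff accessibility.
- PDB I/O: first model, altloc blank/`A`, residues reported with author
  numbering; PB sequences as FASTA (`a`–`p`/`Z`, one record per chain).
- Matrices as labelled whitespace tables; dendrograms as Newick; alignment
  datasets as paired FASTA + metadata TSV + per-column distance track;
  truth bundles as JSON; every CLI stage writes a manifest (config echo,
  input hashes, version).
- All randomness flows through one seeded `numpy` generator;
  identical seeds give byte-identical artifacts.

## Known limitations

- The log-odds scale constant of the original printed formula is not
  recoverable from the source; the implemented convention reproduces the
  sign structure and symmetry the analyses rely on (uniform ⇒ 0) and the
  base/scale are configurable.
- Local alignment is strictly local (no end-trimmed global variant) and the
  gap model is linear; an affine option exists but is off by default.
- Shrake–Rupley here is not NACCESS: absolute RSA values differ by a few
  percent; imported `.rsa` tables bypass the internal calculation entirely.
- The generator's realization map (which label a planted substitution
  surfaces as) is a deterministic property of the prototype geometry; truth
  is therefore defined on realized strings, and recovery statements are
  about realized, not nominal, substitutions.
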