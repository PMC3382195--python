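# pbscope

Protein Block analysis of local structural differences among homologous
proteins.

Homologous protein domains keep their fold but drift in local backbone
conformation, and insertions/deletions concentrate at specific local
motifs.  `pbscope` studies both effects through the **Protein Block (PB)
structural alphabet**: 16 pentapeptide backbone prototypes `a`–`p`, each a
series of 8 dihedral angles (ψ_{i−2}, φ_{i−1}, ψ_{i−1}, φ_i, ψ_i, φ_{i+1},
ψ_{i+1}, φ_{i+2}).  Encoding a 3-D backbone as a 1-D PB string (nearest
prototype by angular RMSD, `Z` at chain termini) turns questions about
local structural change into sequence statistics:

- **Substitution matrices.** From pairwise structural alignments of
  homologs (identity < 40%), PB pairs in the conserved core (aligned Cα
  within 3 Å) are counted, family-size-normalized, and converted to
  symmetric log-odds scores S_ij = log2(q_ij / p_i p_j) — globally, per
  SCOP class, and per solvent-accessibility stratum (exposed/buried at
  7/15/25% RSA, a PB being exposed when ≥ 3 of its 5 residues are
  accessible).
- **Pattern comparison.** Class matrices are compared to the global one
  row by row (Pearson r; rows with r < 0.95 inspected with the 1.5·IQR
  outlier rule) and PBs are clustered on 1 − r with complete linkage.
- **PB-based structure alignment.** Smith–Waterman on PB strings (gap
  penalty −5.0) followed by Kabsch superposition of the aligned Cα pairs;
  matrices are benchmarked by the % of pairs with better/same/worse rmsd.
- **Indel hotspots.** Gap runs flanked by ≥ 3 aligned pairs within 3 Å
  (identity < 80%) are labelled by their flanking di-PB; per insert-length
  class (1–4, 5+), enrichment over the dataset's di-PB background is
  scored with Z = (O − Tp)/√(Tp(1−p)), preferred at Z > 2.

Everything runs on synthetic homolog families: a generator builds ideal
backbones from PB strings (NeRF), applies controlled substitution
processes, plants indels at chosen di-PB contexts, and emits true
alignments with per-column distances plus a truth bundle for recovery
tests.  See `docs/methods.md` for the model details and design choices.

## Worked example

Simulate two SCOP classes whose substitution processes differ only in
where PB `p`'s flux goes, then estimate matrices and locate the planted
difference:

```bash
python analysis/01_simulate_families.py --seed 11 --scale 0.5
python analysis/02_build_substitution_matrices.py
```

prints

```
    class  families  pairs  aligned_columns  core_fraction  median_identity_pct
all-alpha        20     80            40000         0.8351                 24.9
 all-beta        20    120            60000         0.8439                 24.2

200 of 200 pairs pass the identity filter
rows with correlation < 0.95: [('all-alpha vs all-beta', 'b'),
                               ('all-alpha vs all-beta', 'c'),
                               ('all-alpha vs all-beta', 'p')]
```

i.e. ~84% of aligned columns lie in the 3 Å conserved core at these noise
settings, and the row-wise comparison of the two class matrices flags
exactly the rows the planted `p`-flux difference moves (the redirect
surfaces through rows `b`, `c`, `p` because the encoder realizes
substitutions through overlapping windows).  The per-row correlations and
outlier cells land in `results/class_row_correlations.tsv` and
`results/class_outlier_substitutions.tsv`, the matrices in
`results/matrices/*.mat`.

Indel hotspots (insertions planted only at di-PBs `p-a` and `h-i`):

```bash
python analysis/06_indel_hotspots.py --seed 5
```

```
insert_class di_pb  observed  expected     z  preferred modal_context  context_pct
           1    hi        95      5.76 37.69       True        deHIac         11.6
           1    pa       127      5.14 54.38       True        noPAcd         15.0
           2    pa        80      2.96 45.27       True        noPAkl         15.0
          5+    hi        25      1.04 23.84       True        deHIak         12.0
...
```

Both planted di-PBs are flagged (Z ≫ 2) in every length class and no other
di-PB appears; the modal context of the `p-a` hotspot, `noPAcd`, is the
helix C-cap geometry that di-PB encodes.  The remaining drivers cluster
substitution patterns (`03`), benchmark class-specific matrices against the
global one by alignment rmsd (`04`), and build the 32×32 burial-stratified
matrix with its exact 16×16 marginalization check (`05`).

A CLI wraps the same stages for shell use, e.g.

```bash
pbscope simulate --seed 1 --out scratch/ds
pbscope build-matrix --alignments scratch/ds --by-class --out-dir scratch/mats
pbscope align dom1.pdb dom2.pdb --matrix scratch/mats/global.mat --gap -5.0
pbscope indels --alignments scratch/ds --by-class --out scratch/indels.tsv
```

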