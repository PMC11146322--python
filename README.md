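# hotspotsel

Toolkit for locating genomic hotspots of diversifying selection:

- **Branch-model codon likelihood tests** — GY94-style codon substitution
  model (61 sense codons, kappa, omega, F3x4 frequencies by default),
  Felsenstein-pruning likelihoods with analytic branch-length gradients,
  and ML fits of the one-ratio and two-ratio (foreground/background)
  branch models, with chi-square(1) LRTs and Benjamini–Hochberg FDR
  control over a screen.
- **Window clustering statistics** — cumulative-proportion curves of
  candidate vs all genes in consecutive 1-Mb windows, and a permutation
  null for the number of candidates in random fixed-length (default
  12-Mb) windows drawn over randomly re-concatenated chromosomes, plus a
  scan-matched (candidate-label permutation) null for hypothesis-free
  densest-window searches.
- **Synteny-block comparison** — landmark-driven block extraction from
  GFF3 annotations, order/orientation/presence tables, 10-Mb linkage
  classification, and a signed-adjacency breakpoint distance that is
  invariant to whole-linkage-group reversal.
- **Genome metrics** — GC content of coding sequences, per-scaffold
  coverage normalization (grand mean 1), and bimodal-dose detection of
  X-like scaffolds.
- **Synthetic data** — seeded simulators for codon alignments evolved
  under one- or two-ratio models, annotations with planted candidate
  clusters, block rearrangements (inversion / transposition / fission /
  deletion), and coverage matrices with an X-like scaffold. These make
  the whole pipeline testable offline.

## CLI

Installed as `hotspotsel` with subcommands:

```sh
# per-gene branch-model screen with BH FDR (foreground via tag or tree #1 labels)
hotspotsel fit-branch --alignments ALN_DIR --tree tree.nwk \
    --foreground Lasiurus --alpha 0.01 --seed 1 --out fits.tsv

# permutation null for candidate clustering (12-Mb windows, 1000 iters)
hotspotsel scan-cluster --genes genes.gff3 --candidates candidates.txt \
    --window-mb 12 --iters 1000 --seed 1 \
    --observed-window chr3:30000000-42000000 --out null.tsv

# synteny-block extraction and linkage classification
hotspotsel synteny --annotation human=human.gff3 --annotation bat=bat.gff3 \
    --block NF=Nbea,Mab21l1,Dclk1,Sohlh2,Spart,Trpc4,Postn,Foxo1 \
    --block CE=Cecr2,Slc25a18,Atp6v1e1,Bcl2l13,Bid \
    --out synteny.tsv

# GC content and coverage normalization / X detection
hotspotsel gc --fasta cds.fasta --out gc.tsv
hotspotsel coverage --table bedcov.tsv --out coverage.tsv

# synthetic fixtures for any stage
hotspotsel simulate {alignment|genome|blocks|coverage} --seed 1 --out-dir sim/

# end-to-end: fit -> LRT -> FDR -> clustering, from a YAML config
hotspotsel run-all --config config.yaml
```

Every command writes a `.manifest.json` (version, parameters, seeds, input
checksums) next to its output; exit codes are 0 (success), 2 (validation
error), 3 (compute failure).

When `--observed-window` is given, the observed count is tested against the
single-random-window null; without it, a hypothesis-free scan maximum is
reported and tested against a scan-matched label-permutation null so the
empirical P-value stays calibrated.

## Library example

```python
from hotspotsel.io_formats import read_codon_alignment, read_labeled_tree
from hotspotsel.codon_model import fit_one_ratio, fit_branch_model
from hotspotsel.selection_tests import lrt_branch

aln = read_codon_alignment("Fgf9.fasta")
tree = read_labeled_tree("tree1.nwk").prune_to(aln.taxa)
tree.set_foreground(["Lasiurus"])
fit0 = fit_one_ratio(aln, tree)
fit1 = fit_branch_model(aln, tree, init=fit0)
result = lrt_branch(fit0, fit1, gene_id="Fgf9")
print(result.stat, result.p_raw, result.omega_foreground)
```
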