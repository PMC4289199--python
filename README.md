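# recspot

Sequence-based identification of meiotic **recombination hotspots and
coldspots**. Hotspots are 1–2.5 kb genomic regions with elevated
double-strand-break-initiated recombination; they differ from coldspots in
GC content and dinucleotide bias, which makes the problem approachable from
sequence composition alone. `recspot` is for computational biologists who
want to train, inspect and apply such a classifier — on their own labeled
FASTA data or on fully synthetic benchmarks.

## Method

Each DNA sequence `R₁R₂…R_L` is encoded as a **pseudo nucleic acid
composition (PseNAC)** vector:

* **k-mer tiers** — normalized overlapping k-mer frequencies
  `f(m) = count(m) / (L − k + 1)` for k = 1…k_max (default 5), contributing
  `4^k` features per tier;
* **pseudo dinucleotide composition (PseDNC)** — the 16 dinucleotide
  frequencies plus ω global sequence-order factors

  `g_j = (1/(L−j−1)) Σᵢ Δ(RᵢRᵢ₊₁, Rᵢ₊ⱼRᵢ₊ⱼ₊₁)`,

  where `Δ(a,b) = (1/6) Σᵤ (Vᵤ(a) − Vᵤ(b))²` averages squared differences
  of six normalized dinucleotide structural properties (twist, tilt, roll,
  shift, slide, rise; table shipped with the package). The block is
  normalized as `d_m = f_m / (Σf + wΣg)` and `d_{16+j} = w·g_j / (Σf + wΣg)`
  with weight `w` (default 0.05), so it sums to one.

With the defaults (k_max = 5, ω = 10) the merged vector has
4+16+64+256+1024+16+10 = **1390** features. Features are then ranked by
**SVM-RFE**: a linear-kernel soft-margin SVM is refit repeatedly and the
feature with the smallest squared weight `wᵢ²` is eliminated, one per
iteration, yielding a full ranking (an F-score ranker is included as a
baseline). A **grid search** over the regularization parameter C and the
number of top features Dim selects the final model by **jackknife**
(leave-one-out) accuracy, and the report carries sensitivity, specificity,
accuracy, Matthews correlation coefficient and the ROC/AUC of the jackknife
decision values:

```
Sn = 1 − N⁺_mis/N⁺    Sp = 1 − N⁻_mis/N⁻    Acc = 1 − (N⁺_mis+N⁻_mis)/(N⁺+N⁻)
```

A synthetic-data generator produces labeled hot/cold datasets with a
planted, tunable dinucleotide bias (first-order Markov hot class vs i.i.d.
cold class), so the whole pipeline is testable without external data.

## Worked example

```python
import recspot as rs

cfg = rs.SyntheticConfig(n_hot=25, n_cold=30, length_range=(1000, 2500),
                         planted_kmers=(("CG", 3.0),), seed=3)
seqs, labels = rs.generate_dataset(cfg)
X, layout = rs.encode_dataset(seqs, k_max=3, params=rs.PseDncParams(omega=10))
data = rs.LabeledMatrix(X, labels, layout.names)

grid = rs.GridSpec(c_values=(1.0, 32.0), n_values=(4, 8, 16, 32))
report, ranking, result = rs.evaluate_with_grid(data, grid)
print(f"chosen C={report.chosen_c:g}, Dim={report.chosen_dim}")
print(f"Sn={report.sn:.3f} Sp={report.sp:.3f} Acc={report.acc:.3f} "
      f"MCC={report.mcc:.3f} AUC={report.auc:.3f}")
```

prints

```
chosen C=32, Dim=4
Sn=1.000 Sp=1.000 Acc=1.000 MCC=1.000 AUC=1.000
```

— the grid picked C = 32 with the top 4 ranked features, and leave-one-out
classification of the 55 sequences is perfect: with a strong planted CG
enrichment the two classes are linearly separable in PseNAC space. On the
same data `ranking.top(8)` starts with `kmer:CG, kmer:G, pse:CG, …`: the
ranker recovers the planted dinucleotide signal. The `examples/` directory
has one short script per capability (encoding, ranking, full evaluation).

The same pipeline is available as a CLI for shell use:

```sh
recspot simulate --outdir data --n-hot 50 --n-cold 60 --enrich CG:3.0 --seed 1
recspot encode --hot data/hot.fasta --cold data/cold.fasta --out matrix.tsv --k-max 3
recspot rank --matrix matrix.tsv --out ranking.tsv
recspot evaluate --matrix matrix.tsv --outdir results --c-grid 1,32 --n-grid 4,8,16,32
recspot predict --model results/model.json --fasta data/hot.fasta --out calls.tsv
```

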