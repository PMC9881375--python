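# neuropep

A toolkit for **targeted neuropeptidomics** in nematodes: rule-based
discovery of neuropeptide precursor genes in a proteome, design and
scheduling of parallel-reaction-monitoring (PRM) assays, label-free
differential quantification of neuropeptides between life stages,
simulation-based power analysis, detection-overlap statistics, and the
bout statistics of nictation behavior. A synthetic-data module generates
every input the pipeline consumes, so the whole analysis runs end to end
without any external download.

It is aimed at peptidomics practitioners who work with spectral-library
driven PRM workflows (Skyline-style transition reports) and at
behavioral geneticists quantifying dauer/infective-juvenile nictation.

## What it computes

**Precursor discovery.** Neuropeptide precursors are secreted proteins:
a signal peptide followed by mature peptides delimited by dibasic
cleavage sites (KK, KR, RK, RR). A protein is called a candidate
precursor iff it has a signal peptide (calls are supplied as input) and
at least one properly flanked peptide. Mature peptides are cut at
maximal runs of ≥2 basic residues; a C-terminal Gly is consumed as the
amidation donor (−0.98 Da), and N-terminal Gln/Glu flag potential
pyroglutamate (−17.03 / −18.01 Da). Detected peptide lists map back to
precursor genes by exact substring match, and three-set Venn accounting
(detected / predicted / homolog) summarises a species' neuropeptide
complement.

**PRM assay design.** From a spectral library, each peptide's most
intense precursor charge state and its six most intense fragment ions
become an assay target with an RT window (5–10 min full width) around
the library retention time. Targets are packed into the fewest sample
injections such that the number of simultaneously monitored targets
never exceeds the instrument cap (e.g. 50), using greedy first-fit with
an exhaustive optimum available for small instances.

**Differential quantification.** Transition-level reports are filtered
(user-flagged interfering transitions are removed only while ≥5
transitions remain per peptide), fragment areas are summed over
fragments, charge states and Met-ox variants, runs are normalized by
their median MS1-feature abundance, and peptides are retained only when
detected in all replicates of both conditions ("quantifiable") or in
all replicates of exactly one condition ("on/off"); remaining zeros are
imputed with the dataset minimum. Per peptide, a two-sided Student's
*t* test on log10 areas gives *p*, and the fold change is
10^(mean₂ − mean₁).

**Power analysis.** Using per-peptide log10 means and SDs, two-sample
experiments are simulated over a grid of fold changes
{1.1, 1.2, 1.5, 2, 4} × replicate counts {4, 6, 8, 10, 15, 20} (500
simulations per cell, α = 0.05; 30 cells per peptide), recording the
percentage of simulations reaching significance, with a closed-form
noncentral-*t* cross-check.

**Behavior.** Per individual over a fixed window (90 s): nictation
ratio T_nict/T_total, initiation index N_nict/(T_total − T_nict), and
average duration T_nict/N_nict. Group comparisons use a one-way linear
model with Dunnett many-to-one adjustment against the control,
optionally after median inter-experimental (batch) normalization.
Crawling speed comes from centroid tracks (≥30 s, pixel→μm scaled).

## Worked example

Simulate a two-condition (L3 vs dauer) PRM experiment with 4 replicates
per condition and run the differential pipeline:

```python
from neuropep import (SimConfig, generate_proteome,
                      generate_transition_report, DifferentialAbundance)

cfg = SimConfig(seed=4, n_precursors=20, n_decoys=10)
fasta, truth = generate_proteome(cfg)
report, ms1, truth = generate_transition_report(cfg, truth)

model = DifferentialAbundance.from_report(report, ms1, reference="L3")
results = model.fit()
print(results.summary())
```

```
Differential abundance: dauer vs L3
peptides tested: 69 (quantifiable: 69, on/off: 0)
significant at p < 0.05: 40 (39 up in dauer, 1 down)

                   class  mean_log10_L3  mean_log10_dauer  log10_fold_change  fold_change       t         p         q  degenerate
peptide
prec001_p1  quantifiable           3.99              3.95           -0.04015       0.9117  -0.855    0.4254    0.5038       False
prec001_p2  quantifiable          5.044             5.221              0.177        1.503   2.672   0.03693   0.06706       False
prec001_p3  quantifiable          4.402             4.609             0.2075        1.612   5.578  0.001409  0.004859       False
...
```

Each row is one neuropeptide: its per-condition log10 mean areas, the
linear fold change (dauer/L3 — e.g. `prec003_p1` is ≈4.4× more abundant
in dauer), the *t* statistic and two-sided *p* of the Student's *t* test
on the log10 areas, and a Benjamini–Hochberg *q* emitted for reference.
The generator injected fold changes cycling through
{1.1, 1.2, 1.5, 2, 4}, and peptides with small true effects land among
the non-significant rows, as the power analysis predicts for n = 4.
`results.plot_volcano()` draws the corresponding volcano plot with
on/off peptides (detected in a single condition) as triangles.

The same objects are scriptable from the shell:

```bash
neuropep simulate prm --seed 5 --out sim/
neuropep quantify --report sim/transition_report.tsv --ms1 sim/ms1_features.tsv --reference L3 --out results/
neuropep schedule --library lib.tsv --window 10 --cap 50
neuropep nictation --bouts bouts.tsv --control N2
```

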