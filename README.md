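# psas

Solubility-slope indices of amino-acid/amino-acid interactions.

## The problem

Whether a protein forms liquid droplets (liquid–liquid phase separation)
or solid aggregates is driven by pairwise interactions between amino-acid
side chains in water. Classical per-residue scales — aqueous solubility,
side-chain hydrophobicity, hydropathy, secondary-structure propensities,
aromaphilicity — describe a residue's relationship with *water* or with a
*protein fold*, not with another free residue. A direct experimental probe
of residue–residue interactions is the cosolvent solubility assay: dissolve
an aromatic amino acid (Tyr, Trp or Phe, the "solute") to saturation in
buffers containing a second amino acid at increasing concentration (the
"amino acid solvent") and ask whether the solvent residue solubilizes or
insolubilizes the solute.

The index this package computes from such assays is the **PSAS**
(parameter of solubility of an aromatic amino acid in an amino-acid
solvent): with the saturation solubility ratio *r*(*c*) = *s*(*c*)/*s*₀
normalized so that *r* = 1 in plain buffer,

```
PSAS = Δr / Δc        [per M]
```

i.e. the slope of the fitted line of solubility ratio against solvent
concentration *c*. PSAS > 0 marks a *soluble* (droplet-like) interaction,
PSAS < 0 an *insoluble* (aggregate-like) one, and |PSAS| ≤ τ (default
τ = 0.05/M) a neutral solvent. Soluble-solvent columns are expected to
follow the aromaphilicity ordering of the solutes (Trp > Tyr > Phe), and
insoluble-solvent columns the water-solubility or side-chain-hydrophobicity
orderings (Phe > Trp > Tyr or Trp > Phe > Tyr).

The package provides:

* `psas.index_db` — the eight classical amino-acid scales as a packaged
  table, with lookup, ranking and CSV round-trip;
* `psas.assay_sim` — a seeded generator of synthetic assay data with known
  ground-truth slopes, replicate noise and an absorbance/standard-curve
  observation layer;
* `psas.psas_fit` — standard-curve calibration, baseline normalization,
  the slope estimator (fixed intercept at *r* = 1 by default), matrix
  assembly and soluble/insoluble/neutral classification;
* `psas.index_compare` — by-row rank correlations and by-column solute
  orderings of a fitted matrix against the classical scales;
* `psas.seq_profile` — sliding-window profiles of protein sequences with
  any packaged or fitted scale.

## Worked example

```python
from psas import *

scenario = make_scenario("paper_like", seed=1)          # known true slopes
records  = simulate_assay(scenario, Design(n_conc=5, n_reps=3))
matrix   = fit_matrix(records)                          # 20 solvents x 3 solutes
print(matrix.to_frame().round(2).head(7))

classes = classify_matrix(matrix, tau=0.05)
report  = consistency_report(matrix, load_index_set(), classes)
for label in ("soluble", "insoluble", "neutral"):
    print(f"{label}: {', '.join(report.solvent_groups[label])}")
print("Arg column ordering:", column_order(matrix, "Arg"))
```

prints

```
           Tyr    Trp    Phe
solvent
Tyr      69.45  93.33  54.03
Trp       4.68   6.15   4.15
Phe       1.08   1.81   1.28
Arg       0.27   0.29   0.11
Lys      -0.00   0.01  -0.00
His       0.55   0.64   0.46
Pro       0.10   0.11   0.08
soluble: Tyr, Trp, Phe, Arg, His, Pro
insoluble: Ala, Cys, Met, Val, Leu, Ile, Gln, Asn, Glu, Asp
neutral: Lys, Gly, Ser, Thr
Arg column ordering: Trp>Tyr>Phe
```

Each matrix cell is a fitted slope in per-M units: Trp dissolved in a Trp
solvent gains about six ratio units per molar of cosolvent, while Glu and
Asp solvents (further down the table) carry the most negative slopes. The
aromatic solvents show the largest positive values because their usable
concentration range is tiny (Tyr saturates near 3 mM) while the relative
solubility gain at saturation is comparable to the other solubilizers.
Every solubilizing solvent orders the solutes Trp > Tyr > Phe — the
aromaphilicity ordering — and every insolubilizing solvent falls in the
water-solubility/hydrophobicity pair of orderings.

The same pipeline is available from the shell:

```sh
psas simulate --preset paper_like --seed 1 --out assay.csv
psas fit --in assay.csv --mode fixed --tau 0.05 --out psas.tsv
psas compare --assay assay.csv --out report.tsv
psas lookup --index hydropathy --residue Ile      # 4.5
psas profile --fasta seqs.fa --index hydropathy --window 9
```

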