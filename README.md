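# mrmquant

Targeted-proteomics toolkit for **absolute protein quantification by
scheduled MRM with QconCAT internal standards**, plus the downstream
differential statistics used in three-genotype comparative studies. It is a
library first (importable API, narrative scripts under `examples/`), with a
thin `mrmquant` command-line layer for running the workflow from a shell.

Intended users: proteomics method developers and computational biologists
who need to design multiplexed MRM assays in silico, validate that a QconCAT
design actually releases its peptides on digestion, and test quantification
and QC logic against simulated chromatograms with known ground truth before
committing instrument time.

## The method

A *QconCAT* is an artificial protein concatenating one proteotypic peptide
per target protein. Expressed in heavy-isotope medium
((¹³C₆/¹⁵N₂)-Lys, +8.0142 Da; (¹³C₆/¹⁵N₄)-Arg, +10.0083 Da) and spiked into
the sample before LysC + trypsin digestion, it yields one heavy internal
standard per endogenous (light) peptide. For each peptide, three or more
transitions (precursor Q1 → fragment Q3) are monitored on a triple
quadrupole with per-transition voltages computed from linear ramps:

    DP  = 0.049·Q1 + 42.6
    CE  = 0.036·Q1 + 6.9   (2+ precursor)   or   0.054·Q1 − 2.4   (3+)
    CXP = 0.0391·Q3 − 2.23
    EP  = 10

Acquisition is *scheduled*: each transition is monitored only inside a
120-s retention-time window with a 1-s target scan time. Quantification is
the internal-standard identity

    c_endogenous = (Σ light areas / Σ heavy areas) × c_spiked   [fmol/μg]

gated by three QC rules: ratio dot product
rdotp = (L·H)/(‖L‖‖H‖) > 0.9 between the light and heavy per-transition
area vectors, co-eluting apexes, and ≥ 3 transitions surviving
interference elimination. The differential layer provides fold changes,
Welch/Student t tests, volcano selection (|FC| > 1.5 and P < 0.05), one-way
ANOVA with Sidak-adjusted pairwise comparisons (p_adj = 1 − (1 − p)^m), PCA,
and z-scored clustered matrices. Acylcarnitine precursor-ion-scan settings
(common product m/z 85.05; CE −20/−25/−35 V by chain length) are included
for the metabolite side of such studies.

Everything downstream is testable because the package ships its own
simulators: Gaussian light/heavy peak pairs sharing relative transition
intensities (with multiplicative noise, RT jitter, and plantable
interference), and three-group study matrices with planted fold changes.

## Worked example

```python
import mrmquant as mq
from mrmquant.assay import schedule, transitions_to_frame

peptide = mq.Peptide("LVNELTEFAK")
scheduled, report = schedule(mq.build_transitions(peptide, predicted_rt=21.4))
print(transitions_to_frame(scheduled)[["label", "q1", "fragment", "q3", "dp", "ce"]])
```

prints the light/heavy transition pairs

```
 label       q1 fragment        q3      dp      ce
 light 582.3190     y9^1 1050.5466 71.1336 27.8635
 light 582.3190     y8^1  951.4782 71.1336 27.8635
 light 582.3190     y7^1  837.4352 71.1336 27.8635
 heavy 586.3261     y9^1 1058.5608 71.3300 28.0077
 ...
```

— the heavy Q1 sits 8.0142/2 above the light (the Lys label over charge 2),
the y-ion Q3s carry the full shift, and DP/CE follow the ramps above. The
closed loop in `examples/03_simulate_quantify.py` then simulates
chromatograms at 5 % noise with one planted interference and recovers, e.g.

```
         peptide  rdotp  ratio  fmol_per_ug qc_status      dropped_transitions
GLSDGEWQQVLNVWGK    1.0  0.523        5.231      pass GLSDGEWQQVLNVWGK.2.y12.1
  true 5.280  measured 5.231 fmol/ug
```

— rdotp ≈ 1 certifies that the endogenous fragmentation pattern matches the
standard, the interfered transition was eliminated before the ratio was
formed, and ratio × 10 fmol/μg spike returns the simulated truth within ~1 %.

Run the scripts in `examples/` (no arguments) for the designer, the assay
builder, the closed quantification loop and the differential layer; the same
workflow is available from the shell:

```bash
mrmquant design --proteome examples/data/toy_proteome.fasta \
                --targets examples/data/targets.txt --capacity 50 --out-dir out
mrmquant simulate truth --manifest out/manifest.csv --seed 11 --out truth.csv
mrmquant assay --manifest out/manifest.csv --rt truth.csv --out transitions.csv
mrmquant simulate chromatograms --assay transitions.csv --truth truth.csv \
                --seed 11 --out chrom.tsv
mrmquant quantify --chrom chrom.tsv --assay transitions.csv --spikes truth.csv \
                --out quant.csv --rollup proteins.csv
```

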