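# promotif

Promoter motif profiling for TSS-anchored regulatory analysis.

`promotif` is a Python library for asking, over a panel of gene promoters,
*which transcription factors can bind where*: it scans TSS-anchored promoter
windows with position weight matrices (PWMs) at exactly calibrated p-value
thresholds, then derives the analytical products a promoter survey needs —
per-gene upstream/downstream binding-site censuses, master-regulator TF
(MRTF) sets shared by every promoter, gene-specific (exclusive) binders,
autoregulatory self-sites, CArG-box consensus matches, RPKM/RPM expression
ranking, and directed regulatory-network topology. It was built around the
promoter architecture of the *Arabidopsis thaliana* flowering programme
(18 floral promoters, −5000…+1000 around the TSS, hundreds of JASPAR plant
motifs), but every stage is generic.

A seeded synthetic-data module generates matrix libraries of controlled
sharpness, promoters with motifs planted at known positions/strands, and
replicated count matrices — so the entire pipeline is testable end to end
with known ground truth and no downloads.

## The model

A motif of length *L* is scored as a log-likelihood ratio. With count matrix
*n<sub>bj</sub>*, background frequencies *q<sub>b</sub>* and a total
pseudocount *s* distributed across bases proportionally to the background,

&nbsp;&nbsp;&nbsp;&nbsp;*w<sub>bj</sub>* = log₂ [ (*n<sub>bj</sub>* + *q<sub>b</sub>s*) / (*N<sub>j</sub>* + *s*) / *q<sub>b</sub>* ]

and a word scores Σ<sub>j</sub> *w*<sub>w<sub>j</sub>, j</sub> bits. Scores
are discretized onto an integer grid (default 10⁴ units/bit) and the **exact**
null distribution of a random background word's score is computed by
position-wise convolution, so the p-value P(S ≥ s) and the per-matrix score
cutoff for any threshold are exact at grid resolution, not estimates. Every
scan carries two stringencies (p < 10⁻⁴ and p < 10⁻⁵, strict inequality);
stringent hits are a subset of lenient hits by construction. Coordinates are
EPD-style TSS-relative with no position 0; both strands are scanned, and a
hit's `start` is the 5′-most base of the matched window in forward-strand
space.

Downstream definitions: an **MRTF** is a TF with ≥ 1 predicted site in every
promoter of the panel at a given stringency; a **gene-specific TF** has all
of its (lenient-tier) sites in exactly one promoter; an **autoregulatory
site** is a TF's predicted site inside its own gene's promoter. Expression
uses RPKM = C·10⁹/(N·L) and RPM = C·10⁶/N with externally supplied library
sizes N. Network degrees count a self-loop toward out-degree only (the
convention under which the packaged floral network reproduces its published
hub degrees); clustering is computed on the undirected simple projection.

## Worked example

Plant a sharp 10-bp motif at −1024 in a 6-kb promoter and scan it
(`examples/01_scan_planted_promoter.py`):

```python
import promotif as pm

pfms = pm.simulate_pwms(n_matrices=1, length=10, sharpness=0.97, seed=7)
pwm = pm.pfm_to_pwm(pfms[0])
promoters, truth = pm.simulate_promoters(
    ["DEMO01"], pfms, [pm.PlantSpec("DEMO01", pfms[0].matrix_id, -1024, "+")], seed=8
)
for h in pm.scan_promoter(pwm, promoters[0]):
    print(h.start, h.strand, round(h.score_bits, 2), h.pvalue, h.tier)
```

prints

```
-1024 + 19.55 9.5367431640625e-07 stringent
```

— the planted consensus is recovered at exactly −1024 with p-value
4⁻¹⁰ ≈ 9.54 × 10⁻⁷ (one word out of 4¹⁰ scores this high), passing both
thresholds. On the packaged floral network
(`examples/05_network_topology.py`):

```
13 genes, 18 directed edges, self-loops: ['PI', 'SEP3']
SEP3: out_degree 5, in_degree 4   # feeds SEP1/SEP2/SEP4/AG + itself; fed by the four
LFY : out_degree 6, in_degree 0   # activator hub for AP1, AG, SOC1, AGL24, SVP, FUL
```

The other `examples/` scripts cover MRTF/gene-specific identification,
autoregulation + CArG matching, and RPKM/RPM expression ranking.

## Layout

- `src/promotif/motif_io.py` — JASPAR PFM and promoter FASTA I/O, PWM construction
- `src/promotif/scanner.py` — exact score distributions, p-values, scanning
- `src/promotif/profiles.py` — region counts, MRTF/gene-specific/autoregulation/CArG
- `src/promotif/expression.py` — RPKM/RPM, replicate statistics, group ratios
- `src/promotif/network.py` — regulatory networks and topology metrics
- `src/promotif/simulate.py` — seeded synthetic data with ground truth
- `docs/methods.md` — modelling choices, defaults and limitations
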