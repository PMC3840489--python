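# mirpain

A tested, reusable implementation of the computational workflow used to
discover and validate cancer-pain-associated miRNA signatures in sensory
ganglia (dorsal root ganglia, DRG) of tumour-bearing mice. It is aimed at
pain researchers and computational biologists who want to apply — or
stress-test on synthetic data — the combination of:

1. **Replicate-consistency dysregulation screen** on miRNA expression
   arrays. After quantile normalization across arrays, a miRNA is called
   dysregulated at a timepoint when

   ```
   |m_T − m_S| ≥ k · (s_T + s_S)        with  k = 5
   ```

   (m, s: group mean and SD of normalized intensity over biological
   replicates; T = tumour, S = sham) **and** its fold change
   FC = m_T / m_S satisfies FC ≥ 2.5 or FC ≤ 1/2.5. Both bounds are
   inclusive. For n = 3 replicates per group the consistency rule implies
   a worst-case equal-variance two-tailed t-test p of
   2·P(t₄ > 5√3) ≈ 9.8 × 10⁻⁴ ≤ 0.001 (`implied_t_bound`).

2. **ΔΔCт relative quantification** of qPCR Ct tables: per sample
   ΔCт = Cт(target) − Cт(reference) (e.g. sno202 for miRNAs, GAPDH for
   mRNAs), ΔΔCт = mean ΔCт(treatment) − mean ΔCт(control), fold change
   2^(−ΔΔCт), with technical-replicate averaging and QC flags.

3. **Consensus target prioritization**: genes predicted as targets of a
   miRNA by ≥ 2 of 14 prediction algorithms, then filtered by an in-vivo
   expression response — counts normalized to the geometric mean of five
   housekeeping genes (Cltc, Gapdh, Gusb, Hprt, Tubb5), keeping genes
   with inhibitor/control ratio ≥ 1.5 ("at least 50% up-regulation" on
   miRNA inhibition) — plus a reciprocal miRNA–mRNA time-course score.

4. **von Frey psychophysics reduction**: withdrawal frequency as a
   percentage of five stimulations per filament (0.02–1.0 g), mechanical
   response thresholds at a chosen quantile (50% or 80%) by first-crossing
   log-linear interpolation with explicit censoring, and trapezoidal AUC
   of frequency over log10 force.

A synthetic-data module generates all five input kinds with planted,
machine-readable ground truth, so every stage is testable end to end
without animal data.

## Worked example

Run the full synthetic pipeline (simulate → screen → relquant → targets →
behavior) with the default configuration — 615 miRNAs, 26 planted up- and
31 down-regulated at 3-fold with 5% intensity CV, zero-noise Ct tables,
a 10-gene consensus set with 4 planted responders, and a tumour-group
threshold trajectory falling from 0.6 g to 0.05 g over post-implantation
days 0–8:

```bash
mirpain full-run --seed 7 --out-dir demo
```

The end-of-run summary (abridged) reports the recovered funnel:

```json
"screen": {
  "PID-4": {"n_selected": 0, "n_up": 0,  "n_down": 0,  "n_fc_secondary": 0},
  "PID-8": {"n_selected": 55, "n_up": 25, "n_down": 30, "n_fc_secondary": 57}
},
"relquant": {"mmu-sim-miR-0080": 3.0, "mmu-sim-miR-0092": 3.0},
"targets":  {"n_predicted": 10, "n_consensus": 10, "n_responders": 4},
"behavior": {"days": [0, 2, 4, 6, 8], "tumour_final_threshold": 0.036}
```

Reading: at PID-4 (no planted effects) nothing is selected; at PID-8 the
screen recovers 55 of the 57 planted miRNAs at this seed and noise level
with no false positives; zero-noise ΔΔCт recovers the planted 3-fold
induction exactly; the consensus tally and response filter flag exactly
the planted candidate and responder sets; and the estimated 50%
withdrawal threshold of the tumour group has fallen to ≈ 0.04 g by day 8
(planted: 0.05 g, 6 mice). Outputs are TSV/CSV tables with `#` metadata
headers plus a JSON manifest; reruns with the same seed are
byte-identical.

Each stage is also available as its own subcommand (`simulate`, `screen`,
`relquant`, `targets`, `behavior`, `validate`) operating on the documented
CSV contracts, with thresholds exposed as flags (`--k`, `--fc-primary`,
`--min-algorithms`, `--min-ratio`, `--quantile`, ...).

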