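# mlidscan

Single-case methylation-array analysis for detecting **multi-locus
imprinting disturbance (MLID)** in patients with genomic imprinting
disorders such as Beckwith–Wiedemann syndrome (BWS) and Silver–Russell
syndrome (SRS).

Imprinted differentially methylated regions (iDMRs) are methylated on one
parental allele only, so in bulk blood DNA they sit near β ≈ 0.5 on an
Infinium methylation array. An epimutation — loss of methylation (LoM) or
gain of methylation (GoM) — shifts a patient's β away from the control
band at the probes of the affected region. Some patients carry such shifts
not only at their disease locus (ICR1 = *H19/IGF2*:IG-DMR or ICR2 =
*KCNQ1OT1*:TSS-DMR on 11p15.5) but at additional iDMRs: that is MLID.

`mlidscan` is aimed at analysts working with small clinical cohorts —
a handful of controls, a dozen patients — where ordinary group statistics
do not apply and each patient must be tested individually.

## The method

1. **Probe QC** — drop probes failing detection p ≥ 0.05 (in any sample by
   default), SNP-associated probes, cross-reactive probes, chrX/chrY
   probes, then probes with missing values.
2. **BMIQ normalization** (per sample) — fit three-state (unmethylated /
   hemi-methylated / methylated) beta mixtures to Infinium type I and
   type II probes separately and quantile-map the type II states onto the
   type I components, correcting the type II dynamic-range compression.
3. **Single-case testing** — for each patient and probe, the
   Crawford–Howell t-test against the n controls:

   t = (x − x̄_c) / (s_c · √((n+1)/n)),  df = n − 1,

   with Δβ = x − x̄_c. A differentially methylated position (DMP) requires
   |Δβ| > 0.2 **and** p < 0.05 (both strict).
4. **Region calling** — an iDMR is aberrant when it holds ≥ 4 significant
   probes including ≥ 2 consecutive probes (genomic order) of the same
   direction; mixed-direction regions are never aberrant.
5. **Epigenotype & MLID** — the epigenotype is read off ICR1/ICR2
   (IC2-LoM, IC1-GoM, IC1-LoM, …); a patient has MLID when ≥ 1 additional
   non-excluded iDMR is aberrant. Polymorphically imprinted regions
   (*VTRNA2-1*) never count.
6. **Cohort level** — group DMPs (|mean Δβ| > 0.2, Welch p < 0.05),
   hierarchical clustering of samples, per-patient DMP count tables, plus
   the clinical scores (BWS consensus score, NH-CSS), pyrosequencing %mC
   standard-deviation scores, Fisher exact and Mann–Whitney comparisons.

A synthetic-cohort generator with planted epimutations (beta-distributed
noise, mosaic-fraction attenuation, type II compression, detection
failures) makes every stage testable end to end with known ground truth.

## Worked example

Simulate a cohort of 4 controls and 2 patients, with patient P1 carrying
an IC2-LoM epimutation plus a second hypomethylated iDMR (*PPIEL*), and
run the full pipeline:

```bash
cat > sim.yaml <<'YAML'
seed: 7
n_patients: 2
n_background_probes: 150
planted_events:
  - {patient_id: P1, region_name: "KCNQ1OT1:TSS-DMR", direction: LoM, effect_size: 0.3}
  - {patient_id: P1, region_name: "PPIEL:Ex1-DMR", direction: LoM, effect_size: 0.3}
YAML
mlidscan simulate --config sim.yaml --out data
# wrote synthetic cohort (246 probes x 6 samples) to data

cat > run.yaml <<'YAML'
beta_path: data/beta.tsv
roles_path: data/roles.tsv
manifest_path: data/manifest.tsv
catalog_path: data/catalog.tsv
detection_p_path: data/detection_p.tsv
output_dir: out
YAML
mlidscan run --config run.yaml
```

`out/filter_report.json` shows the QC funnel (246 probes in, 1 removed by
detection, 1 cross-reactive, 2 on sex chromosomes, 242 retained). The
per-patient region table `out/regions_P1.tsv` contains, among others:

```
region             n_probes  n_significant  max_consecutive  mean_abs_delta  direction  aberrant
PPIEL:Ex1-DMR      8         8              8                0.310           hypo       True
KCNQ1OT1:TSS-DMR   7         7              7                0.292           hypo       True
VTRNA2-1:DMR       8         0              0                0.000           none       False
```

and `out/mlid_P1.json` gives the verdict:

```json
{
  "patient_id": "P1",
  "epigenotype": "IC2-LoM",
  "disease_regions": ["KCNQ1OT1:TSS-DMR"],
  "additional_aberrant_regions": ["PPIEL:Ex1-DMR"],
  "mlid": true
}
```

P1's disease epigenotype is IC2-LoM (mean |Δβ| ≈ 0.29 over 7 significant
probes at the *KCNQ1OT1* region), and the additional hypomethylation at
*PPIEL* (|Δβ| ≈ 0.31, 8 significant probes) makes the patient
MLID-positive. The unplanted patient P2 comes out `"epigenotype": "none",
"mlid": false`.

The same stages are available as library functions
(`mlidscan.analyze_cohort`, `mlidscan.crawford_howell`,
`mlidscan.call_region`, …) for use without the CLI.

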