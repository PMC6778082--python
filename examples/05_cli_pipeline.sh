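#!/bin/sh
# Full shell pipeline: simulate a small rendered experiment, extract
# phenotypes, run the dose-response analysis.
#
# The config below scales the design down (4 conditions, 2 worms, 2 time
# points, a 583 um chamber) so the whole pipeline finishes in a couple of
# minutes; drop the overrides for the full 8-condition design.

set -e

cat > /tmp/wormpheno_demo.yaml <<'YAML'
outdir: /tmp/wormpheno_demo
seed: 3
chamber_px: 448
n_worms_per_cond: 2
timepoints_h: [12.0, 24.0]
concentrations: [0.0, 1.0e-6, 1.0e-5, 1.0e-4, 1.0e-3]
analysis_times_h: [24.0]
noise_sd: 0.02
growth:
  L_max_um: 420.0
  L0_um: 160.0
  t_mid_h: 14.0
  k_h: 0.15
  ic50_growth: 4.6e-5
  hill_growth: 1.2
  ic50_motility: 5.0e-6
  hill_motility: 1.0
YAML

wormpheno simulate -c /tmp/wormpheno_demo.yaml
wormpheno phenotype /tmp/wormpheno_demo/manifest.csv -c /tmp/wormpheno_demo.yaml
wormpheno doseresponse /tmp/wormpheno_demo/phenotypes.csv \
    -c /tmp/wormpheno_demo.yaml \
    --embryo-table /tmp/wormpheno_demo/embryo_table.csv

echo
echo "IC50 summary:"
cat /tmp/wormpheno_demo/doseresponse/ic50_summary.csv
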