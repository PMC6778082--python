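# Column dictionaries

## manifest.csv

| column | meaning |
|---|---|
| clip_path | clip file relative to the manifest's directory (multi-page TIFF) |
| worm_id | unique worm identifier; (worm_id, time_h) pairs are unique |
| condition_mol | compound concentration in mol/L; 0 = control |
| time_h | hours post-hatch at recording |

## phenotypes.csv (one row per worm x time point)

| column | meaning |
|---|---|
| worm_id, condition_mol, time_h | provenance (as in the manifest) |
| length_um | median centerline arclength over valid frames (µm); empty = QC failure, never 0 |
| area_um2 | median segmented worm area (µm²) |
| central_velocity_um_s | centroid path length / spanned time (µm/s) |
| beating_freq_hz | thrashes per second from mid-body bend zero crossings |
| head_amplitude_um | cumulative path of the head tip over the clip (µm) |
| tail_amplitude_um | cumulative path of the tail tip over the clip (µm) |
| head_excursion_um | secondary: max distance of head tip from its mean position |
| tail_excursion_um | secondary: max distance of tail tip from its mean position |
| responsive | True if convex hull of travel > pi * length² |
| n_valid_frames | frames with a usable mask and centerline |
| qc_freq_unreliable | frequency estimate near the fps/2 sampling limit |
| qc_orientation_unconfident | head/tail path lengths differ by < 10% |
| error | present only for unreadable clips: the reason the row is empty |

A sibling `phenotypes.qc.json` holds the per-clip QC report (flags and
free-text notes).

## embryo_table.csv (one row per embryo)

| column | meaning |
|---|---|
| embryo_id | unique embryo identifier |
| condition_mol | concentration (mol/L); 0 = control |
| twitch_time_h | first muscle twitching (h after experiment start) |
| hatch_time_h | hatching time; empty if the embryo never hatched |
| died_as_l1 | True if the hatched larva died during L1 (False for unhatched) |

## doseresponse/percent_response.csv

| column | meaning |
|---|---|
| condition_mol | concentration (mol/L); 0 = control |
| time_h | time point (h); empty for the time-averaged index |
| phenotype | phenotype column name |
| n | worms contributing |
| mean, sem | raw condition mean and standard error |
| percent, percent_sem | percent of the control mean at the same time point |

## doseresponse/ic50_summary.csv

| column | meaning |
|---|---|
| phenotype, time | what was fitted ("time-averaged" for the index) |
| ic50_mol | fitted IC50 (mol/L); empty when refused |
| ic50_label | human-readable IC50 with SI prefix, or "no_ic50" |
| r2, top, bottom, hill | 4PL fit quality and parameters (% of control) |
| verdict | "ok" or "no_ic50" |
| reason | why the fit was refused (empty when ok) |
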