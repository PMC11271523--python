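# Desk-scale synthetic cohort (the default test surface):
# 6 patients x 2 samples covering 7 phenotypic categories across the three
# disease stages, 500x500 px cores at 0.18 um/pixel, 100 cells per sample.
# Omitted keys fall back to the CohortConfig defaults (state proportions,
# per-state morphologies, duct geometry).
n_patients: 6
samples_per_patient: 2
categories: [P0, P1, P3, P5, P7, P9, P10]
pixel_size_um: 0.18
image_size_px: 500
cells_per_sample: 100
assortativity: 0.0
duct_fraction: 0.12
noise_sd: 0.02
bg_level: 0.05

# Reference-only full-scale cohort shape
# (122 patients, 560 samples, 11 categories); not intended for CPU desk use:
#   n_patients: 122
#   samples_per_patient: 5
#   categories: [P0, P1, P2, P3, P4, P5, P6, P7, P8, P9, P10]
#   cells_per_sample: 500
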