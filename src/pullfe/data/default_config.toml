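# Default two-system pulling experiment: apo-like vs holo-like toy landscapes.
# The bound well of each system is calibrated by exact quadrature so the true
# breaking free energy F(unbound) - F(bound) matches target_delta_f; their
# difference (apo - holo) defines the ligand-induced stabilization recovered
# by the pipeline.  Units: kJ/mol, nm, ps, K.

[landscape.apo]
hbond_thresholds = [0.12, 0.25]
bounds = [-0.06, 0.41]
target_delta_f = -2.5
wells = [
    { shape = "rect", center = 0.04, depth = 9.0, half_width = 0.06, softness = 0.01 },
    { shape = "rect", center = 0.31, depth = 12.0, half_width = 0.05, softness = 0.01 },
]

[landscape.holo]
hbond_thresholds = [0.12, 0.25]
bounds = [-0.06, 0.41]
target_delta_f = 1.9
wells = [
    { shape = "rect", center = 0.04, depth = 13.5, half_width = 0.06, softness = 0.01 },
    { shape = "rect", center = 0.31, depth = 12.0, half_width = 0.05, softness = 0.01 },
]

[protocol]
spring_constant = 3.9e4   # (kJ/mol)/nm^2
lambda_start = 0.0        # nm
lambda_end = 0.35         # nm
velocity = 1.75e-4        # nm/ps  (0.175 nm/ns over 2 ns)
dt = 5e-3                 # ps
temperature = 300.0       # K
diffusion = 6e-4          # nm^2/ps
save_stride = 2000        # record one analysis frame every 10 ps

[analysis]
stride = 1                # WHAM denominator uses every recorded slice
bound_min_count = 1       # n >= 1 hydrogen bonds counts as bound
position_bins = 60

[bootstrap]
n_resamples = 200
seed = 97531

[seeds]
apo = 100000
holo = 200000

[run]
n_replicas = 512
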