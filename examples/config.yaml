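# Example pipeline configuration.
#
# Only keys you want to change need to appear; everything else takes the
# study defaults (see otogeo.config.Config).  The growth-model parameters
# below are illustrative placeholders that reproduce plausible length/age
# ranges for Antarctic toothfish -- replace them with the published von
# Bertalanffy estimates for your stock before interpreting ages.

growth_l_inf: 180.0     # cm
growth_k: 0.09          # per year
growth_t0: -0.5         # years
radius_length_slope: 0.0714286   # cm of fish length per um of otolith radius

# change-point sampler (protocol defaults shown)
bcp_p0: 0.2
bcp_w0: 0.2
bcp_n_iter: 10000
bcp_burn_in: 5000

# mixture model
mixture_g_min: 1
mixture_g_max: 5
mixture_n_restarts: 20

# geo-location
mc_iterations: 5000
capture_radius_km: 100.0
capture_layer_m: 100.0
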