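"""Fit FRAP recovery for a fast client probe and a slow scaffold.

Raw region-of-bleach / whole-field traces are generated with whole-field
acquisition bleaching; the ratio normalization cancels it, and the
first-order fit A(1 - exp(-t/tau)) returns the mobile fraction and
half-life t_1/2 = ln2 * tau.
"""

import numpy as np

from condensate_proximity import fit_trace, generate_frap_trace

LN2 = np.log(2)

for label, amplitude, t_half, dt, t_post in [
    ("client", 0.86, 18.3, 1.0, 120.0),
    ("scaffold", 0.46, 156.0, 5.0, 900.0),
]:
    trace = generate_frap_trace(
        amplitude=amplitude,
        tau_s=t_half / LN2,
        whole_field_decay_rate=1e-3,   # 0.1%/s acquisition bleaching
        noise_sd=0.01,
        dt_s=dt,
        t_pre_s=10 * dt,
        t_post_s=t_post,
        seed=7,
    )
    fit = fit_trace(trace)
    print(
        f"{label:9s} mobile fraction A = {fit.amplitude_A:.3f}, "
        f"tau = {fit.tau_s:6.1f} s, t_half = {fit.t_half_s:6.1f} s, "
        f"residual RMS = {fit.residual_rms:.3f}"
    )
# Clients recover several-fold faster than scaffolds and with a higher
# mobile fraction: they exchange with the dilute phase, while much of the
# scaffold network is immobile on this timescale.
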