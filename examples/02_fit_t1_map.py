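"""Fit the three-parameter IR model per pixel and recover the T1 map.

Simulates a noiseless MOLLI series from a known phantom slice, fits
S(t) = A - B exp(-t/T1*) per pixel with polarity restoration, applies the
Look-Locker correction T1 = T1*(B/A - 1) and compares against the source.
"""

import numpy as np

import synthlge as sl

maps, truth = sl.make_lv_phantom(
    sl.PhantomConfig(scar_specs=(sl.ScarSpec(0, 45, 90, 0.7),))
)
series = sl.simulate_molli(maps[0])
fitted = sl.fit_t1_map(series)

myo = truth.myocardium_masks[0]
err = np.abs(fitted.values - maps[0].values)
print(f"max |fit - truth| over the whole slice: {np.nanmax(err):.2e} ms")
print(f"mean myocardial T1: truth {maps[0].values[myo].mean():.1f} ms, "
      f"fit {fitted.values[myo].mean():.1f} ms")
print(f"unconverged pixels: {(~fitted.quality_mask).sum()}")

# single-curve reference fit on one scar pixel
r, c = np.argwhere(truth.scar_masks[0])[0]
fit = sl.fit_molli(series.tis, series.images[:, r, c])
print(f"\nscar pixel ({r},{c}): T1* = {fit.t1_star:.1f} ms, B/A = {fit.B/fit.A:.3f}, "
      f"T1 = {fit.t1:.1f} ms (truth 300)")
# A noiseless fit reproduces the source T1 to machine precision; the
# Look-Locker identity T1 = T1*(B/A - 1) holds exactly.
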