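"""Compute synthetic phase-sensitive IR images at arbitrary inversion time.

From a post-contrast T1 map, S(TI) = 1 - 2 exp(-TI/T1) gives an IR image at
any TI retrospectively: the default series is 40 images from TI 200 ms in
25 ms steps. Normal myocardium nulls at TI = T1 ln 2; below that, short-T1
scar is hyperintense — the enhancement contrast used for scar detection.
"""

import numpy as np

import synthlge as sl

maps, truth = sl.make_lv_phantom(
    sl.PhantomConfig(scar_specs=(sl.ScarSpec(0, 120, 80, 0.8),))
)
series = sl.synthesize_series(maps[0])
print(f"series: {series.n_images} images, TIs {series.tis[0]:.0f}..{series.tis[-1]:.0f} ms")

ti = sl.optimal_ti(maps[0], truth.myocardium_masks[0] & ~truth.scar_masks[0],
                   grid=sl.TIGrid())
print(f"TI nulling remote myocardium (T1 500 ms): {ti:.0f} ms  (500 ln2 = {500*np.log(2):.1f})")

idx = int(np.argmin(np.abs(series.tis - ti)))
img = series.images[idx]
scar_signal = img[truth.scar_masks[0]].mean()
myo_signal = img[truth.myocardium_masks[0] & ~truth.scar_masks[0]].mean()
print(f"at TI {series.tis[idx]:.0f} ms: scar signal {scar_signal:+.3f}, "
      f"remote myocardium {myo_signal:+.3f}")
# Scar is bright while nulled myocardium sits near zero — exactly the
# contrast a conventional late-enhancement image displays.
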