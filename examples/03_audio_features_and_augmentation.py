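"""Audio preprocessing: energy trim, five augmentations, log-mel features.

Generates one fall and one daily-activity clip, shows the crest factor
(peak/RMS) separation, the sixfold augmentation bookkeeping, and the
log-mel image the CNN classifier consumes.
"""

from fusefall import (
    augment,
    crest_factor,
    energy_gate_trim,
    expand_dataset,
    gen_audio,
    logmel,
    to_image,
)

fall = gen_audio("fall", seed=4)
daily = gen_audio("not-fall", seed=4)
print(f"fall clip crest factor:  {crest_factor(fall):5.1f}  (impact transient)")
print(f"daily clip crest factor: {crest_factor(daily):5.1f}  (footsteps only)")

trimmed = energy_gate_trim(fall, threshold_db=-40.0)
print(f"\nenergy-gate trim: {fall.duration:.2f} s -> {trimmed.duration:.2f} s "
      f"(leading/trailing near-silence removed)")

louder = augment(fall, "volume_up")
restored = augment(louder, "volume_down")
err = abs(restored.samples - fall.samples).max()
print(f"volume_up then volume_down restores the waveform to {err:.1e}")

expanded = expand_dataset([fall, daily], seed=0)
print(f"augmentation: 2 clips x (original + 5 methods) = {len(expanded)} clips")

spec = logmel(fall)
image = to_image(spec, size=48)
print(f"\nlog-mel spectrogram: {spec.matrix.shape[0]} mel bands x "
      f"{spec.matrix.shape[1]} frames; resized to {image.shape[1:]} for the CNN")
col_energy = spec.matrix.max(axis=0)
print(f"brightest time frame: {int(col_energy.argmax())} "
      f"(the impact transient's broadband column)")
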