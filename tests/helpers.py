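"""Shared test utilities."""

import numpy as np

from harpipe.synthetic import ActivityModel, default_activity_models


def scaled_activity_models(effect: float, n_channels: int = 3):
    """Interpolate the default class models toward their common mean.

    ``effect=1`` is the default class separation; ``effect=0`` collapses all
    classes onto identical signal statistics (chance-level discriminability).
    """
    base = default_activity_models(n_channels)
    mean_amp = float(np.mean([m.amplitudes[0] for m in base]))
    mean_freq = float(np.mean([f for m in base for ch in m.base_freqs for f in ch]))
    out = []
    for m in base:
        freqs = tuple(
            tuple(mean_freq + effect * (f - mean_freq) for f in ch)
            for ch in m.base_freqs
        )
        amps = tuple(mean_amp + effect * (a - mean_amp) for a in m.amplitudes)
        out.append(
            ActivityModel(
                class_id=m.class_id,
                name=m.name,
                base_freqs=freqs,
                amplitudes=amps,
                noise_sd=m.noise_sd,
                drift=m.drift,
            )
        )
    return out
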