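"""Published in-vivo group summaries used as calibration inputs.

The porcine study delivered 6000 V, 0.02 s-dose treatments at a 45 degC
setpoint with four exposed-electrode lengths and reported, per group, the
replicate count, treatment time and CT-reconstructed ablation volume
(mean +/- SD).  These measured summaries are the inputs to threshold
calibration and to the synthetic-cohort generator; nothing here is a model
output.
"""

from __future__ import annotations

import pandas as pd

#: Measured group summaries: exposure (cm), replicates, treatment time (s),
#: ablation volume (cm^3), mean ablation length/width (cm).
REFERENCE_GROUPS = pd.DataFrame(
    [
        (0.5, 9, 473.0, 83.0, 7.95, 3.74, 2.8, 2.2),
        (1.0, 6, 421.0, 91.0, 11.56, 5.32, 3.2, 2.5),
        (1.5, 7, 314.0, 63.0, 12.83, 2.61, 3.7, 2.7),
        (2.0, 5, 250.0, 105.0, 7.64, 2.50, 3.5, 1.8),
    ],
    columns=["exposure_cm", "n", "time_mean_s", "time_sd_s",
             "volume_mean_cm3", "volume_sd_cm3",
             "length_mean_cm", "width_mean_cm"],
)

EXPOSURES_CM = tuple(REFERENCE_GROUPS["exposure_cm"])
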