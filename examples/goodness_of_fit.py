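"""Goodness of fit of the generic model against a noisy synthetic panel.

Simulates one plant per TLN with realistic measurement noise, predicts each
profile with the packaged generic parameters, and reports RMSE and R^2 per
trait — the same summaries used to judge predictions against observations.
"""

import numpy as np

from leafsize import (
    SimConfig,
    SpeciesId,
    default_parameter_set,
    evaluate_fit,
    generate_dataset,
    predict_profile,
)

cfg = SimConfig(species=SpeciesId.MAIZE, tln_values=[15, 17, 19, 21],
                plants_per_tln=5, seed=7)
records, _ = generate_dataset(cfg)
pset = default_parameter_set("maize")

predictions = {
    tln: predict_profile(pset, tln) for tln in records["tln"].unique()
}
for column, attr in (("blade_length_mm", "length_mm"),
                     ("blade_width_mm", "width_mm")):
    obs = records[column].to_numpy()
    pred = np.concatenate([
        predictions[row.tln].__getattribute__(attr)[row.position - 1:row.position]
        for row in records.itertuples()
    ])
    stats = evaluate_fit(obs, pred)
    print(f"{column}: RMSE {stats['rmse']:.1f} mm, R^2 {stats['r2']:.3f} "
          f"(n = {len(obs)})")

print(
    "\nRMSE reflects the simulated measurement noise (sd 20 mm length, "
    "3 mm width); R^2 near 1 means the profile shape explains nearly all "
    "of the position-to-position variation."
)
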