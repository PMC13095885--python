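"""Parameter recovery: simulate a maize panel, then calibrate from scratch.

Generates a noiseless multi-TLN panel from the packaged maize parameters,
runs the full calibration pipeline (per-TLN-group nonlinear fits, xs and dr
regressions on TLN, pooling of the fixed parameters) and compares the
recovered parameters with the generating truth.
"""

from leafsize import (
    NoiseSpec,
    SimConfig,
    SpeciesId,
    Trait,
    calibrate_species,
    default_parameter_set,
    generate_dataset,
)

cfg = SimConfig(
    species=SpeciesId.MAIZE,
    tln_values=list(range(13, 23)),
    plants_per_tln=1,
    noise=NoiseSpec(length_sd=0.0, width_sd=0.0),
    seed=1,
)
records, truth = generate_dataset(cfg)
print(f"simulated {len(records)} leaf records over TLN 13-22")

result = calibrate_species(records)
fitted = result.parameter_set.trait(Trait.BLADE_LENGTH)
generating = default_parameter_set("maize").trait(Trait.BLADE_LENGTH)

print("\nblade length: generating -> recovered")
for name in ("L1", "cm", "rm", "tb", "dsl"):
    print(f"  {name:>3}: {getattr(generating, name):8.2f} -> "
          f"{getattr(fitted, name):8.2f}")
print(f"  xs rule: {generating.xs_rule} ->\n           {fitted.xs_rule}")
print(f"  dr rule: {generating.dr_rule} ->\n           {fitted.dr_rule}")
print(
    "\nWith noiseless input the generating curve is inside the model family, "
    "so every parameter is recovered to optimizer precision; the per-group "
    f"fit RMSEs are all below {result.group_results['rmse'].max():.1e} mm."
)
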