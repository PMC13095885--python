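# Packaged generic parameter sets for the expolinear-logistic leaf size
# model: species -> trait -> fixed parameters {value, se}, the xs(TLN) rule
# and the dr(TLN) rule.  Units are mm for L1/dsl, mm per leaf for cm,
# per-leaf rates for rm/dr, leaf-position units for tb and the xs rule.
shape_factors:
  standard: 0.71
  flag: 0.635
tln_range: [8, 45]
species:
  maize:
    blade_length:
      L1: {value: 51.18, se: 0.79}
      cm: {value: 123.84, se: 3.1}
      rm: {value: 1.17, se: 0.12}
      tb: {value: 2.02, se: 1.14}
      dsl: {value: 12.53, se: 1.49}
      xs_rule:
        type: linear
        a: {value: 1.10, se: 0.55}
        b: {value: 0.47, se: 0.03}
      dr_rule:
        a: {value: 2.88, se: 0.30}
        b: {value: -0.13, se: 0.02}
        xs: {value: 17.63, se: 0.34}
    blade_width:
      L1: {value: 15.98, se: 0.06}
      cm: {value: 19.37, se: 1.7}
      rm: {value: 0.58, se: 0.05}
      tb: {value: 4.10, se: 0.40}
      dsl: {value: 0.20, se: 0.04}
      xs_rule:
        type: linear
        a: {value: 5.97, se: 0.55}
        b: {value: 0.25, se: 0.03}
      dr_rule:
        a: {value: 7.81, se: 0.8}
        b: {value: -0.41, se: 0.05}
        xs: {value: 17.13, se: 0.22}
  sorghum:
    blade_length:
      L1: {value: 17.59, se: 0.79}
      cm: {value: 70.5, se: 1.45}
      rm: {value: 1.56, se: 0.15}
      tb: {value: 1.92, se: 0.17}
      dsl: {value: 3.50, se: 0.70}
      xs_rule:
        type: segmented
        a: {value: 4.64, se: 0.72}
        b: {value: 0.46, se: 0.04}
        c: {value: 0.26, se: 0.02}
        bp: {value: 20.50}
      dr_rule:
        a: {value: 2.62, se: 0.2}
        b: {value: -0.08, se: 0.01}
        xs: {value: 27.02, se: 1.36}
    blade_width:
      L1: {value: 4.20, se: 0.06}
      cm: {value: 11.72, se: 0.21}
      rm: {value: 0.61, se: 0.02}
      tb: {value: 4.04, se: 0.15}
      dsl: {value: 0.18, se: 0.03}
      xs_rule:
        type: segmented
        a: {value: 7.31, se: 0.76}
        b: {value: 0.25, se: 0.04}
        c: {value: 0.20, se: 0.02}
        bp: {value: 20.50}
      dr_rule:
        a: {value: 1.78, se: 0.18}
        b: {value: -0.05, se: 0.01}
        xs: {value: 29.00, se: 2.9}
  pearl_millet:
    blade_length:
      L1: {value: 34.51, se: 0.79}
      cm: {value: 62.69, se: 3.14}
      rm: {value: 0.92, se: 0.12}
      tb: {value: 1.53, se: 0.28}
      dsl: {value: 1.37, se: 0.41}
      xs_rule:
        type: linear
        a: {value: 7.16, se: 0.5}
        b: {value: 0.31, se: 0.03}
      dr_rule:
        a: {value: 5.15, se: 0.71}
        b: {value: -0.22, se: 0.04}
        xs: {value: 19.87, se: 0.9}
    blade_width:
      L1: {value: 7.06, se: 0.06}
      cm: {value: 14.99, se: 3.14}
      rm: {value: 0.19, se: 0.02}
      tb: {value: 14.79, se: 1.69}
      dsl: {value: 0.08, se: 0.02}
      xs_rule:
        type: linear
        a: {value: 5.11, se: 3.63}
        b: {value: 0.40, se: 0.17}
      dr_rule:
        a: {value: 2.97, se: 4.04}
        b: {value: -0.11, se: 0.21}
        xs: {value: 22.00, se: 8.13}
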