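# 6 MV photon budget with a barometer meeting the +/-1 mbar recommendation
# (instead of the worst-case +/-8 mbar default). Everything else inherits
# the default budget. Run with:
#   tg51mc run --config examples/photon_good_barometer.yaml --n 1000000
modality: photon
inherit_defaults: true
sources:
  pressure:
    distribution: uniform
    half_width: 1.0
    unit: mbar
    user_controlled: true
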