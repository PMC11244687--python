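# Budget configuration schema

A budget document is YAML (or JSON) with three top-level keys:

```yaml
modality: photon          # or electron  (required)
inherit_defaults: true    # unlisted sources fall back to the defaults
sources:                  # one block per overridden source
  pressure:
    distribution: uniform # normal | uniform
    sigma: 1.0            # OR half_width (uniform only); giving both
    unit: mbar            #   inconsistently is an error
    user_controlled: true # optional; defaults to the canonical class
  stability:
    distribution: normal
    sigma: 0.003          # relative fraction for percent-valued sources
```

Rules:

* Without `inherit_defaults: true`, every source consumed by the chain must
  be listed; a missing source is a validation error.
* `sigma` and `half_width` are interchangeable for uniform sources via
  `sigma = half_width / sqrt(3)`; normal sources take `sigma` only and are
  never truncated.
* Percent-valued sources (`unit: rel`, the default for them) store relative
  fractions: `0.004` means 0.4 %.  Physical sources must declare their
  canonical unit explicitly (`cm`, `degC`, `mbar`, `pct_dd`).
* Unknown source names, negative widths and wrong units raise errors naming
  the offending source.

## Canonical source names

Photon: `SSD, depth_meas, depth_scan, temperature_A, temperature_B,
pressure, field_size, kQ_intrinsic, kQ_formula, repeatability, stability,
extracameral, electrometer_calibration, chamber_calibration,
interim_formula, pion_formula, humidity`.

Electron: `SSD, dset, I50, R50_formula, temperature_A, temperature_B,
pressure, kecal, kprime_formula, repeatability, stability, extracameral,
electrometer_calibration, chamber_calibration, pion_formula, humidity`.

User-controlled by default: SSD, depths (`depth_meas`, `depth_scan`,
`dset`), temperature, pressure, field size and `I50`; everything else
(chamber/electrometer calibration, protocol data, formula accuracies,
stability, repeatability, extracameral, humidity) is not.

An example override file ships in `examples/photon_good_barometer.yaml`.
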