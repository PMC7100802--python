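# Configuration file schema

`load_config` / `save_config` (and every CLI `--tissue/--scheme/--bounds`
option) accept JSON or YAML files with a `kind` discriminator.  Units follow
the conventions of the printed literature tables: **T1 in seconds, T2 in
milliseconds, TR in milliseconds, flip angles in degrees, exchange rates in
1/s, off-resonance in Hz**.  Internally everything is converted to seconds.

## Tissue (`kind: tissue`)

```yaml
kind: tissue
t1f: 0.45      # s
t1s: 1.4       # s
t2f: 15        # ms
t2s: 90        # ms
mwf: 0.15      # fraction, 0 <= mwf < 1
kfs: 8         # 1/s
delta_f: 0     # Hz, optional (default 0)
```

## Bound set (`kind: bound_set`)

Each entry is `[lower, upper]` with `lower < upper` and `lower >= 0`:

```yaml
kind: bound_set
t1f: [0.2, 0.7]    # s
t1s: [0.8, 2.0]    # s
t2f: [2, 40]       # ms
t2s: [60, 160]     # ms
mwf: [0.0, 0.5]
kfs: [0.5, 20]     # 1/s
```

## Acquisition scheme (`kind: scheme`)

```yaml
kind: scheme
tr_spgr: 6.5                                   # ms
tr_ssfp: 6.5                                   # ms
fa_spgr: [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]  # deg
fa_bssfp180: [2, 6, 14, 22, 30, 38, 46, 54, 62, 70]
fa_bssfp0: [2, 6, 14, 22, 30, 38, 46, 54, 62, 70]  # may be empty
```

Validation errors name the offending field.  `save_config` followed by
`load_config` round-trips every object exactly.
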