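# Force-volume container format (version 1.0)

One map per HDF5 file. All lengths are nm, forces pN, moduli kPa, spring
constants N/m. The pixel grid is 0-based `(row, col)`, row-major. Curve
segments are stored in acquisition (time) order: approach with increasing
piezo displacement z, retract with decreasing z; larger z means the piezo is
extended further toward the sample.

```
/                          attrs: format_version = "1.0"
/acquisition               attrs (all float64):
    spring_constant        cantilever k, N/m
    tip_radius             apex radius R, nm
    poisson_ratio          sample Poisson ratio
    setpoint_force         imaging force trigger, pN
    pixel_size             lateral pixel pitch, nm
    temperature            K
/curves/approach_z         float64 (rows, cols, n)
/curves/approach_f         float64 (rows, cols, n)
/curves/retract_z          float64 (rows, cols, n)
/curves/retract_f          float64 (rows, cols, n)
/channels/<name>           float64 (rows, cols); NaN = pixel excluded
                           names: height, e_pm, e_cortex, adhesion_force
/masks/specific            uint8 (rows, cols)        optional
/masks/stratum             int8  (rows, cols)        optional
                           0 non-adhesive, 1 cholesterol, 2 indeterminate,
                           -1 unassigned
/events/<column>           one dataset per column    optional
                           row, col (int64); rupture_force_pN,
                           rupture_distance_nm, Lc_nm, Lp_nm, rms_pN
                           (float64); specific (uint8)
/truth/                    synthetic ground truth    optional
    e_pm_true              float64 (rows, cols), kPa
    e_cortex_true          float64 (rows, cols), kPa
    domain_mask            uint8 (rows, cols)
    height_true            float64 (rows, cols), nm  optional
    events                 float64 (n_events, 6):
                           row, col, rupture_force_pN, rupture_sep_nm,
                           Lc_nm, Lp_nm
    attrs: p_bind, rupture_mean, rupture_sd, noise_sd,
           drift_c0, drift_c1, drift_c2, seed
```

Writer guarantees: attributes written in sorted order, datasets created in a
fixed order with `track_times=False`, no compression — two writes of the
same map yield byte-identical files. Curves are stored at float64, so
`read_dataset(write_dataset(m))` round-trips curves bit-exactly.

Channel exports (`export_channels`): one 32-bit float greyscale TIFF and one
CSV per channel, plus `events.csv` with columns
`row,col,rupture_force_pN,rupture_distance_nm,Lc_nm,Lp_nm,rms_pN,specific`.
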