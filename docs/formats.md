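# File formats

All outputs are plain, diff-able text. Floats are serialised with `%.17g`
so read-write round-trips are exact. Readers reject files whose first-line
schema tag mismatches, with the offending line quoted.

## Time series (`timeseries.csv`)

```
# hipposim-timeseries v1
t,N,X2_max,X2_mean,X2_min,X3_max,X3_mean,X3_min,n_cyan,n_orange,n_blue,n_red
0,2,0.2,0.2,0.2,0,0,0,0,2,0,0
...
```

One row per recorded step: simulated time (s), cell count, max/mean/min of
nuclear (X2) and phosphorylated (X3) YAP/TAZ over cells (µM), and per-colour
counts (cyan/blue = arrested in M/G1, orange/red = growing in M/G1). Counts
sum to N.

## Snapshot (`final_snapshot.csv`)

```
# hipposim-snapshot v1 t=<s> k=<step> zeta=<ratio> next_id=<int>
id,t,x,y,z,vx,vy,vz,sigma,radius,age,color,X1,X2,X3,rho
```

One row per cell: id, time, position (µm), velocity (µm/s), size parameter
and physical radius (µm), age since division (s), colour index 0–3,
concentrations (µM), packing fraction. `read_snapshot` reconstructs the
population field-for-field.

## Extended XYZ (`final_snapshot.xyz`)

Standard extended-XYZ for 3D viewers (OVITO, ASE, VMD): first line is the
cell count, second line declares
`Properties=species:S:1:pos:R:3:radius:R:1:x2:R:1 Time=<s>`, then one row
per cell with the colour name as the species (`cyan`, `orange`, `blue`,
`red`), the position, the radius and nuclear YAP/TAZ.

## Configuration (`config.yaml`)

YAML with sections `reaction`, `mechanics`, `cycle` (hours: `T_CC_h`,
`T_M_h`), `simulation`, plus `preset` and `initial_concentrations`. The
shipped presets under `src/hipposim/presets/` are complete examples;
`hipposim run` flags override file values.
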