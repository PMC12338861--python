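# anisopy

Rotational-rate decomposition of multi-wavelength steady-state fluorescence
anisotropy, and assembly of membrane depth x temperature fluidity gradients.

Depth-graded n-(9-anthroyloxy) fatty acid probes (2-AS, 7-AS, 9-AS, 12-AS,
16-AP) report rotational mobility at graded depths of a lipid bilayer.
Measuring their steady-state emission anisotropy r at several excitation
wavelengths — each with its own fundamental anisotropy r_o and excited-state
lifetime tau_F — linearizes the rotating-plates model into

    Y = R_ip * X + R_op
    X = (10 r_o - 1) / (5 r_o + 1)
    Y = 5 r_o (r_o / r - 1) / (2 tau_F (5 r_o + 1))

so a weighted linear regression across wavelengths yields the in-plane
(R_ip, slope) and out-of-plane (R_op, intercept) rotation rates, reported
in MHz with 95% confidence intervals, plus rotational correlation times
phi = 1/(6 R). Applying this per temperature window of a slow thermal ramp
(12 degC/h, 10 -> 52 degC, five alternating excitation wavelengths) and
smoothing over temperature produces R_op(T) / R_ip(T) profiles per probe,
which are arranged on a (attachment carbon) x (temperature, 5 degC steps)
grid and compared cell-wise between membrane conditions.

A synthetic-instrument module forward-simulates the whole experiment
(ground-truth Arrhenius rate laws -> anisotropies -> four polarized
intensity channels with noise), so every stage is testable without
instrument data.

## Modules

| module | contents |
| --- | --- |
| `anisopy.anisotropy` | polarized readings, r = (R_v - R_h)/(R_v + 2 R_h), range flags, CSV dialect |
| `anisopy.photophysics` | tau_F / r_o anchor tables, temperature interpolation, synthetic default |
| `anisopy.decomposition` | (X, Y) transform, weighted fit, correlation times |
| `anisopy.thermal` | temperature windows, profile smoothing, gradient surfaces and comparisons |
| `anisopy.simulate` | scenarios, forward model, noise, study generation |
| `anisopy.cli` / `anisopy.config` | command-line workflow and run configuration |

## CLI

```sh
# simulate a two-condition study (30 CSV runs + manifest)
anisopy simulate --scenario sensitive.json --scenario resistant.json --out study/

# readings -> anisotropy table
anisopy anisotropy --in study/sensitive_2-AS_r1.csv --out anis.csv

# readings -> windowed rate decompositions (pooled replicates)
anisopy decompose --in study/sensitive_2-AS_r1.csv --in study/sensitive_2-AS_r2.csv \
    --in study/sensitive_2-AS_r3.csv --out decomp_sensitive.csv

# decompositions -> gradient surfaces (+ cross-condition comparisons)
anisopy gradient --in decomp_sensitive.csv --in decomp_resistant.csv --out gradients/

# fold change between two surfaces
anisopy compare --a gradients/surface_sensitive_op.csv \
    --b gradients/surface_resistant_op.csv --out fold.csv
```

Scenario files are the JSON dump of `anisopy.simulate.SyntheticScenario`
(see `sensitive_like_scenario()` / `resistant_like_scenario()` /
`modulator_pair_scenarios()` for ready-made factories). A run
configuration (`--config`) is the JSON dump of `anisopy.config.RunConfig`.

Without `--photophysics`, commands fall back to a clearly-labeled
*synthetic* lifetime/fundamental-anisotropy table intended for tests and
simulations; real analyses must supply their own measured table
(CSV: probe_id, temperature_c, excitation_nm, tau_f_ns, r_o).

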