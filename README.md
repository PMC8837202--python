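# forcejump

Analysis pipeline for optical-tweezers **force-jump** experiments on
protein–ligand **catch bonds** — interactions whose lifetime *increases*
with dissociative tension up to a critical force and decreases beyond it.
The motivating system is the MIDAS domain of the ribosome-biogenesis AAA
mechanoenzyme Mdn1 binding the ubiquitin-like domains of the assembly
factors Rsa4 and Ytm1, but every stage is generic for the assay geometry.

In the assay, a single-stranded DNA *bridge* (55 or 70 nt unpaired) runs in
parallel with a *loading* path consisting of two 12-nt oligonucleotide
segments and the bound protein pair (modeled as an inextensible 8 nm rod).
The trap alternates a 0.5 pN low force (binding permitted) with a 4–12 pN
high force; if the proteins are bound at the jump, an intermediate position
is held for the bond lifetime τ and then steps by Δx when the bond ruptures.

The package covers the full chain:

- **`forcejump.mechanics`** — worm-like-chain elasticity,
  `F·Lp/kBT = ¼(1−x/Lc)⁻² − ¼ + x/Lc`, and the two-spring circuit
  `F_Tot(x) = F_Bridge(x + L_prot) + F_Load(x)` that partitions trap force
  and predicts Δx(F_Tot).
- **`forcejump.detection`** — per-plateau event extraction: centering on the
  first five samples, effective noise eSD (median of 10-point boxcar SDs),
  a two-state one-way Gaussian HMM (emitters at 0 and +4 eSD, final state
  absorbing) decoded with Viterbi, a ≥4-sample acceptance filter, and
  automated drift/instantaneity screens.
- **`forcejump.kinetics`** — survival probability S(t) = 1 − ECDF,
  single-exponential fits `S = A·e^{b·t}`, and mean-lifetime summaries
  (1/τ̄ is the off-rate).
- **`forcejump.models`** — the two-pathway catch-slip Bell model

  τ̄⁻¹(F) = k_c⁰·exp(F·x_c/k_BT) + k_s⁰·exp(F·x_s/k_BT),  x_c < 0 < x_s,

  with the closed-form critical force
  F\* = k_BT·ln(−k_c⁰x_c/(k_s⁰x_s))/(x_s−x_c), plus the single-site
  binding isotherm Y = Y_max·[S]/(K_D+[S]) for titration data.
- **`forcejump.simulate`** — a ground-truth simulator of whole force-jump
  sessions (200 Hz, ≥5 s plateaus, exponential lifetimes following the
  catch-slip law, circuit-model steps, noise, drift, instrument response)
  and of 1:2 serial-dilution titrations.
- **`forcejump.pipeline` / `forcejump` CLI** — `simulate`, `detect`, `fit`,
  `run-all` over TSV traces + JSON sidecars, CSV event tables and JSON
  reports, driven by a validated YAML config.

## Worked example

`examples/04_catch_slip_fit.py` simulates ten molecules per bridge
construct with the Rsa4-like parameters
(k_c⁰ = 5.3 s⁻¹, x_c = −2.0 nm, k_s⁰ = 0.01 s⁻¹, x_s = 4.1 nm) as ground
truth, detects every event, pools mean lifetimes on the protein-load axis
and refits the Bell model:

```
 construct  F_Tot_pN  F_Load_pN  n_events  mean_tau_s  sem_tau_s
        55       4.0      1.368        24       0.363      0.059
        55       6.0      2.649        29       0.811      0.160
        ...
        70      12.0      8.474        12       0.043      0.005

                     fit     truth
kc0 (1/s)           6.97      5.30
xc (nm)            -2.78     -2.00
ks0 (1/s)         0.0363    0.0100
xs (nm)             3.16      4.10
F_crit (pN)         3.53      3.72
```

Mean bond lifetime rises from ~0.4 s at ~1.4 pN of protein load to ~0.8 s
near 3 pN and collapses to tens of milliseconds above 8 pN — the chevron
shape of a catch bond — and the refitted critical force lands within a
few tenths of a pN of the ground truth.  The other examples demonstrate
the mechanical circuit table (Δx grows from 3.4 to 6.1 nm over 4–12 pN on
the 55 nt bridge and 6.4 to 11.5 nm on the 70 nt bridge), single-trace
event detection, survival fitting, and K_D recovery (6.9 ± 2 μM scale)
from noisy titrations.

The same chain runs from a shell:

```bash
forcejump run-all --seed 6 --out workdir/
```

## Layout

```
src/forcejump/    library (mechanics, detection, kinetics, models,
                  simulate, io, config, pipeline, cli, plots)
examples/         one narrative script per capability
tests/            pytest suite, including end-to-end acceptance checks
scripts/          acceptance.py
docs/methods.md   model assumptions, parameter choices, limitations
```
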