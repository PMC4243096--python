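# tumorclock

Waiting-time clocks for multistage tumour progression with a
time-inhomogeneous driver-mutation rate.

## The problem

Colorectal and pancreatic tumours progress through well-defined clinical
stages (microadenoma → adenoma → carcinoma → metastasis) as cells
accumulate *driver* mutations. Classical multistage models assume a
constant mutation rate, yet successive drivers are observed to arrive
faster and faster. `tumorclock` models the driver count of a cell as an
inhomogeneous Poisson process whose rate grows exponentially,

    mu(t) = mu0 · exp(b·t),   b = a·s,

where `mu0` is the initial driver-mutation rate per cell per generation,
`s` the selective advantage coefficient and `a` a transform factor linking
selection to the curvature of the rate law. The mean driver count at time
`t` is the cumulative intensity `lambda(t) = (mu0/b)(e^{bt} − 1)`, the
stage occupancies are Poisson, `p_j(t) = lambda^j e^{−lambda}/j!`, and a
`k`-driver stage becomes detectable in a pool of `N` sensitive cells when
`p_k = 1/N`, at the threshold intensity

    lambda_k = −k·W0( −(k!)^{1/k} / (k·N^{1/k}) )   (exact, Lambert W)
    lambda_k ≈ (k!/N)^{1/k}                          (linearized)

with waiting time `t_k = ln(b·lambda_k/mu0 + 1)/b` generations. Because
only the product `b = a·s` is identifiable from timing data, the library
fits `(b, mu0)` per patient from short stage timelines and splits `b`
only when one factor is known externally.

The package is for modellers of somatic evolution who want per-patient
progression clocks: closed forms, two independent numerical oracles
(master-equation integration, seeded stochastic simulation), published
literature clocks for comparison, and a small CLI.

## Worked example

```python
import tumorclock as tc

# first colorectal patient: mu(t) = 2e-5 * exp(0.0032 t)
params = tc.ProgressionParams(mu0=2e-5, s=0.01, a=0.32)
table = tc.waiting_time_table(params, n_cells=1e10, k_max=12)
print(table.to_frame()[["k", "lambda_k", "t_generations", "t_years", "stage"]])
```

prints (rounded):

```
 k  lambda_k  t_generations  t_years         stage
 1  0.000000            0.0     0.00
 2  0.000014            0.7     0.01
 3  0.000843           39.6     0.43  microadenoma
 4  0.006999          234.8     2.57 small_adenoma
 5  0.026052          513.3     5.63 large_adenoma
 ...
12  0.776297         1509.4    16.54     carcinoma
```

Reading: at a 4-day generation time, the third driver — the microadenoma
founder — is expected once among 10^10 cells after ~40 generations
(~0.4 y), the 5-driver large adenoma after ~5.6 y, and the 12-driver
carcinoma after ~16.5 y. The `lambda_k` column is the detection threshold
intensity for each `k`; `lambda_k` at `k=1` is `1/N`.

Fitting a noisy timeline back:

```python
stages = tc.StageDefinition.from_mapping(
    {"microadenoma": 3, "small_adenoma": 4, "large_adenoma": 5,
     "early_carcinoma": 8, "carcinoma": 12})
tl = tc.generate_synthetic_timeline(params, 1e10, stages, noise_sigma=0.1, seed=1)
fit = tc.fit_progression_params(tl)
print(fit.b_hat, fit.mu0_hat)   # ~0.0032, ~2e-5
```

The same operations are available from the shell:

```sh
tumorclock lambda-table --mu0 2e-5 --s 0.01 --a 0.32 \
    --n-cells 1e10 --k-max 16 --out thresholds.tsv
tumorclock synth --mu0 2e-5 --s 0.01 --a 0.32 --n-cells 1e10 \
    --noise-sigma 0.1 --seed 1 --out patient.tsv
tumorclock fit --timeline patient.tsv --fix-s 0.01 --out fit.json
tumorclock simulate --mu0 0.01 --b 0 --t-end 100 --n-cells-sim 20000 \
    --seed 1 --out occupancy.tsv
```

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.

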