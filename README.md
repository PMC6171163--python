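# ctrlshare

Power and type-1-error calculus for **two-stage case-control studies that
share control samples between the discovery and replication stages**.

In a standard two-stage GWAS (method **A**) a variant is declared a hit when
it passes a discovery threshold (`p_d < α`, cases `C1` vs controls `C0`), a
replication threshold in independent samples (`p_r < β`, `C1'` vs `C0'`),
and a meta-analytic threshold (`p_m < γ`, pooled cases vs pooled controls),
with all effects in the same direction.  When control samples are expensive
or hard to ascertain, the discovery controls can be *re-used* at replication:
method **B** compares `C1'` against `C0 ∪ C0'`, and method **C** uses the
pooled control set at both stages.  Sharing correlates the stage-wise
Z-statistics under the null, so keeping `β` unchanged would inflate the
false-positive rate.  This package:

* derives the null correlations `ρ_ij` of the five signed Z-statistics
  (`z_d, z_r, z_s, z_c, z_m`) from the four cohort sizes alone, and builds
  the per-method covariance matrices `Σ_A, Σ_B, Σ_C` (`Σ_C` is always
  singular; `Σ_A`, `Σ_B` are singular iff `n0/n1 = n0'/n1'`);
* solves the adjusted replication thresholds `β*` (method B) and `β⊥`
  (method C) so the joint null hit rate
  `P0 = 2·Pr(z_d > z_α, z_r > z_β, z_m > z_γ)` is conserved exactly
  (`β⊥ < β* < β` always), using a deterministic trivariate-normal tail
  engine accurate deep into genome-wide tails;
* computes power curves over log-odds ratio for a variant with a given mean
  minor-allele frequency, average/maximum power differences between methods,
  and the number of extra independent controls that would buy the same power;
* profiles type-1 error under *aberrance* (systematic confounding of one or
  more cohorts' allele frequencies), including closed-form large-aberrance
  bounds;
* validates every analytic quantity against a seeded binomial Monte-Carlo
  simulator of the full pipeline.

It is aimed at statistical geneticists and biostatisticians planning or
re-analysing replication studies — typical uses are conventional GWAS with a
control-rich discovery cohort, inter-disease comparisons where controls are
scarce, and studies whose replication controls are weakly ascertained.

## Worked example

A study with 15000 discovery controls, 5000 discovery cases and 5000/5000
replication samples, at thresholds `α = 5e-6`, `β = 5e-4`, `γ = 5e-8`:

```sh
$ ctrlshare adjust --n0 15000 --n1 5000 --n0p 5000 --n1p 5000 \
    --alpha 5e-6 --beta 5e-4 --gamma 5e-8
   n0   n1  n0p  n1p  alpha   beta  gamma         beta_star         beta_perp                p0          residual        rho_ds  rho_cs  rho_dm
15000 5000 5000 5000  5e-06 0.0005  5e-08 1.27040550112e-05 1.11995277365e-05 1.13207641445e-09 4.75628852218e-24 0.19364916731     0.2    0.75
```

Sharing the 15000 discovery controls correlates discovery and replication
(`ρ_ds ≈ 0.194`), so the replication threshold must drop from `5e-4` to
`β* ≈ 1.27e-5` to keep the joint null hit rate at `P0 ≈ 1.13e-9`.  Even
under that stricter threshold, the pooled 20000-strong control set makes the
shared design more powerful:

```sh
$ ctrlshare compare --n0 15000 --n1 5000 --n0p 5000 --n1p 5000
method_x method_y    avg_integral  avg_window        avg_mean  max_difference   argmax_log_or         beta_star         beta_perp
       B        A 0.0112063832641           1 0.0112063832641 0.0639388791332 -0.207858765654 1.27040550112e-05 1.11995277365e-05
```

Method B's power exceeds method A's by up to 6.4 percentage points (at
log-odds-ratio ≈ ±0.21 for a variant with mean MAF 0.1), and by 1.1
percentage points averaged over the log-OR window where the methods differ.
Matching that with an independent-controls design would take ~2200 extra
replication controls:

```sh
$ ctrlshare parity --n0 15000 --n1 5000 --n0p 5000 --n1p 5000 --log-or -0.2079
 extra_controls        power_b        power_a  capped
           2159 0.640115113083 0.640125662389   False
```

Other subcommands: `power` (full curves), `error-profile` (type-1 error
under aberrance of a chosen cohort), `simulate` (Monte-Carlo validation),
`scan` (a design table at once).  Everything is also available as a library
(`ctrlshare.solve_adjusted`, `ctrlshare.power_at_log_or`, ...).

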