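# aquakrig

Machine-learned, flexible, polarizable water models at desk scale: atomic
energies and atomic multipole moments of the water monomer are learned by
kriging (Gaussian-process regression) from labelled configurations, and the
resulting models drive molecular-dynamics simulations of water clusters with
rank-truncated multipolar electrostatics.

## Who this is for

Researchers developing or studying machine-learned force fields built on an
atomistic energy partition: the package implements the complete workflow --
training-set generation, labelling, quality filtering, model training and
validation, dynamics, and structural analysis -- against a fully analytic
surrogate labelling oracle, so every stage can be run, tested and profiled
on a laptop without any quantum-chemistry software.

## The model

Every atomic property *Y* (an atomic energy `E_A`, or one real spherical
multipole component `Q_lm` in the atom's body-fixed frame) is a kriging
model over the monomer's internal coordinates `f = (r_OH1, r_OH2, theta)`:

    Y(f) = mu + sum_j a_j exp( - sum_h theta_h |f_h - f_h,j|^p_h ),

with weights `a = R^-1 (y - mu 1)` so the model interpolates its training
data, and hyperparameters `theta_h > 0`, `p_h in (0, 2]` chosen by
maximising the concentrated log-likelihood with particle-swarm optimisation
(`p_h` may also be fixed at 2).

During dynamics the total potential of a cluster of flexible monomers is

    E = sum_mol sum_A E_A(f)  +  sum_AB sum_lm Q_lm^A T^AB Q_l'm'^B  +  E_LJ,

where the electrostatic sum runs over intermolecular atom pairs and is
truncated at overall interaction rank `L = l_A + l_B + 1` (L = 1: charges
only; L = 3 adds charge-dipole, dipole-dipole and charge-quadrupole), and
`E_LJ` is a shifted 12-6 potential with Lorentz-Berthelot combining rules.
Because the moments are re-predicted from the current monomer geometry every
step, the electrostatics respond to intramolecular distortion -- the model's
polarization mechanism -- and the forces include these moment-gradient terms
exactly.

Training configurations come from stochastic normal-mode displacement of the
equilibrium monomer (r = 0.9619 A, theta = 105.05 deg), constrained to at
most 20% distortion of every internal coordinate; labelled configurations
are discarded when the net molecular charge exceeds 0.001 e or any atom's
integration-error figure L(Omega) exceeds a threshold (10^-4 or
5 x 10^-5 Ha).

## Worked example

```python
from aquakrig import (
    EnsembleFilterPolicy, PSOSettings, WaterForceField, WaterModelSet,
    filter_ensemble, initialize_cluster, label_ensemble, mae,
    run_simulation, sample_configurations, seed_configuration,
    split_train_validation,
)

# 1. sample and label a monomer ensemble
configs = sample_configurations(seed_configuration(), n=1200, rng_seed=1)
labelled = label_ensemble(configs, rng_seed=2)
kept = filter_ensemble(labelled, EnsembleFilterPolicy())
print(f"filter kept {len(kept)}/{len(configs)} configurations")

# 2. train the monomer model set (3 energies + 27 moment components)
train_set, valid_set = split_train_validation(kept, n_trn=50, rng_seed=3)
models = WaterModelSet.train(
    train_set,
    pso=PSOSettings(swarm_size=40, iterations=150),
    moment_pso=PSOSettings(swarm_size=16, iterations=60),
    rng_seed=4,
)
print(models.energy[0].summary())
print(f"energy MAE: {mae(models.energy, valid_set, 'energy'):.3f} kJ/mol")
charge_models = [atom[0] for atom in models.moments]
print(f"charge MAE: {mae(charge_models, valid_set, 'charge'):.3f} me")

# 3. a thermostatted 8-molecule cluster run at rank L = 3
ff = WaterForceField(models, L=3)
state = initialize_cluster(n_mol=8, rng_seed=5, temperature=300.0)
frames, log = run_simulation(ff, state, n_steps=2500, dt=1.0, rng_seed=6)
print(f"mean temperature: {log.temperature_K.iloc[1000:].mean():.1f} K")
print(f"max net force:    {log.net_force.max():.2e} kJ/mol/A")
```

Output:

```
filter kept 1076/1200 configurations
Kriging model results
======================================================
Property:            energy:O
N_trn:               50
Trend mean mu:        686.8133
Process var sigma^2:  51816.247
Nugget (absolute):    7.412e-08
Concentrated loglik: -42.754948
Feature        theta          p
------------------------------------------------------
r_OH1              3.7528          2
r_OH2             5.30252          2
theta_HOH        0.202552          2
------------------------------------------------------
Max training residual: 8.446e-02
energy MAE: 0.188 kJ/mol
charge MAE: 1.150 me
mean temperature: 316.6 K
max net force:    1.31e-12 kJ/mol/A
```

The filter removes ~10% of configurations (net-charge and integration-error
screens); a 50-point energy model already predicts the summed atomic
energies of held-out configurations to ~0.2 kJ/mol and the net molecular
charge to ~1 me; the cluster run holds its target temperature under the
Andersen thermostat, and the total force on the cluster vanishes to
rounding (the polarization force terms are exact gradients).

A command-line interface mirrors the pipeline stages
(`aquakrig sample | label | train | validate | simulate | analyze |
pipeline`); `aquakrig pipeline --workdir out/` runs everything with
defaults, skipping already-completed stages on rerun.

## Limitations

The labelling oracle is a synthetic surrogate with realistic magnitudes,
not an electronic-structure method; see `docs/methods.md` for exactly what
it does and does not emulate. Electrostatics are direct-space and
non-periodic (free clusters only), atomic multipoles stop at the
quadrupole, and dispersion-repulsion is a fixed Lennard-Jones term.
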