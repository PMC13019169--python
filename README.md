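# arraycrit

Near-critical conformational-spread dynamics of bacterial chemosensory
arrays: a kinetic Monte Carlo 2D Ising simulator with sensory-adaptation
feedback, the single-cell FRET switching-statistics pipeline, and the
finite-size scaling analysis that locates the array's coupling energy
relative to the Ising critical point.

## The problem

The *E. coli* chemosensory array is a membrane-associated lattice of
thousands of receptors, CheA kinases and CheW scaffolds whose summed kinase
activity is the cell's chemotactic signal. Single-cell FRET recordings of
cells dominated by one large array show spontaneous two-state switching of
the entire kinase population — the hallmark of strongly cooperative,
near-critical collective dynamics. This package provides the computational
machinery to model and quantify that behaviour:

- **Conformational-spread model.** An L x L lattice of allosteric units with
  spins σ_i = 2a_i − 1 and energy (k_BT units)

      H = −J Σ_<ij> σ_i σ_j + Σ_i (H_b,i/2 + H_L/2) σ_i,

  simulated by rejection-free kinetic Monte Carlo with flip rates
  ω_i = ω₀ exp[−J σ_i Σ_j σ_j + (h_i/2) σ_i] that satisfy detailed balance
  exactly. Methylation feedback (H_b,i = α(m₀ − m_i); active units
  demethylate, inactive units methylate) produces robust perfect adaptation
  to a₀ = k_R/(k_B + k_R). Bond disorder (Tar/Tsr receptor mixing) and
  ligand-field step protocols are supported.
- **Switching statistics.** Activity traces (from FRET preprocessing or
  simulation) are low-pass filtered, switching events detected as
  derivative peaks, and each event annotated with its amplitude, residence
  time Δt and transition time τ (saturating-exponential fit). Derived
  statistics: activity bias ⟨a⟩ and ΔG = ln[(1−⟨a⟩)/⟨a⟩], Arrhenius
  residence fits ⟨Δt_up,down⟩(ΔG) = ⟨Δt⟩ e^(−γ ΔG), exponential dwell fits,
  energy landscapes −ln p(a), the dimensionless timescale ratio
  r = ⟨Δt⟩/⟨τ⟩ and the noise strength η = σ_a/a₀.
- **Finite-size scaling.** Sweeps over (L, J) measure r per point through an
  acquisition-emulating analysis chain; near criticality
  r ≈ L^(z−b) exp(c₀ εL) with ε = |J* − J|/J, while the finite-size critical
  coupling shifts as J*(L) = J*(∞)/(1 − 1.25/L), J*(∞) = ln(1+√2)/2 ≈ 0.44.
  Constant-r isolines J_r^iso(L) are compared against J*(L), and the
  fundamental flip frequency is calibrated as ω₀ = r c_τ L^b / Δt_exp.
- **Response analysis.** Step-stimulus ensembles quantify the trade-off
  between response amplitude (1 − ⟨a⟩/0.5) and response speed (1/t_R), with
  and without adaptation feedback.
- **Synthetic data.** Every estimator can be scored against generators with
  exact ground truth: telegraph activity with exponential dwells and finite
  transition ramps, full fluorescence-level FRET cells with photobleaching
  and noise, cohorts with imposed Arrhenius structure, and 1D
  cluster-intensity profiles.

## Worked example

```python
from arraycrit.scaling import sweep_point

# a 12 x 12 array just above its finite-size critical coupling
# (jstar_of_L(12) = 0.492), measured through the acquisition-emulating chain
rec = sweep_point(12, 0.5, events_target=100, seed=1)
print(f"n_events = {rec.n_events}, polarized = {rec.polarized}")
print(f"<dt> = {rec.mean_dt:.0f}/omega0  <tau> = {rec.mean_tau:.0f}/omega0  r = {rec.r:.1f}")
```

prints

```
n_events = 112, polarized = True
<dt> = 719/omega0  <tau> = 53/omega0  r = 13.6
```

i.e. the array switches as a unit (polarized two-state histogram), spends
~700 flip times (≈ 22 s at the calibrated 1/ω₀ = 30 ms) in each state and
traverses between states in ~50 flip times, giving a dimensionless
timescale ratio r ≈ 14 — switching statistics of the same character as the
experimental recordings (r ≈ 9–12), as expected a couple of per cent above
J*(L).

A command-line interface mirrors the library:

```bash
arraycrit simulate --config sim.json --out trace.csv
arraycrit synth --n-cells 50 --seed 1 --out-dir bundle/
arraycrit fret --traces bundle/traces.csv --windows bundle/windows.json --out act.csv
arraycrit events --activity act.csv --windows bundle/windows.json \
          --out events.csv --summary cells.csv
arraycrit sweep --config sweep.json --out sweep.csv
arraycrit isoline --r 9 --r 12 --sweep sweep.csv --out isolines.csv
```

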