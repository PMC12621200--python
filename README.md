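# orcakit

Analysis pipeline for discovering small-molecule **activators of OGG1**
(8-oxoguanine DNA glycosylase 1), the base-excision-repair enzyme whose
AP-lyase step is rate-limiting. Organocatalytic switches ("ORCAs") bind the
active site and accelerate catalytic turnover; because the same site must
also admit the DNA substrate, their dose-response is **bell-shaped**: the
incision rate rises with activator occupancy and declines again at high
concentration.

The package implements every quantitative step of such a discovery
campaign, from raw plate-reader traces to trajectory hydration analysis,
together with a synthetic-data generator so the whole pipeline is testable
without any instrument data:

| stage | module | what it computes |
|---|---|---|
| simulation | `orcakit.synthetic` | kinetic plates, microsomal decay, transwell transport, MD-like trajectories — all with known ground truth |
| incision kinetics | `orcakit.kinetics` | linear-window detection, initial rates (OLS slope), % activation of the APE1 full-turnover control, Michaelis–Menten saturation |
| potency | `orcakit.dose_response` | bell-model fit A(c) = a_max · c/(c+k_a) · k_i/(k_i+c), rising-limb **AC50** with censoring, activator/inhibitor/inactive calls, 100 µM primary-hit rule |
| compound metrics | `orcakit.metrics` | pAC50 = −log₁₀(AC50 [M]), AcLE = (1.37/#HA)·pAC50, AcLLE = pAC50 − clogP, docking LE = −score/#HA with the 0.40 triage threshold, fold-selectivity |
| in-vitro PK | `orcakit.pk` | microsomal k_el/t₁/₂/Cl_int (log-linear regression, 0.42 mg protein/mL), Caco-2 P_app = V_A/(A·t)·(acc/donor), efflux ratio and P-gp calls, kinetic solubility |
| trajectories | `orcakit.traj` | Kabsch superposition RMSD, RMSF, ligand–water-oxygen RDF g(r), waters within 5 Å, average-linkage clustering with representative frames |
| formats & CLI | `orcakit.io`, `orcakit.cli` | long-format plate CSV, multi-model PDB / extended XYZ trajectories, YAML run config, `orcakit` command |

## Worked example

The numbered drivers under `analysis/` run the full campaign on synthetic
data and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py      # generates results/data/
python analysis/02_incision_kinetics.py
python analysis/03_dose_response.py
python analysis/04_compound_metrics.py
python analysis/05_pk_analysis.py
python analysis/06_trajectory_analysis.py
```

The dose-response stage prints (plate simulated with a true AC50 of
0.50 µM, triplicates, 2% read noise):

```
ORCA-1: activator, AC50 = 0.516 uM (true 0.500), hit=True
bell fit: a_max 109.1%, rising midpoint k_a 0.600 uM, falling midpoint k_i 52.3 uM
```

i.e. the fitted curve crosses 50% of the APE1-control turnover at
0.52 µM — within 4% of the generator's ground truth — and the compound
passes the AC50 < 100 µM primary-hit rule. The PK stage reproduces the
transport arithmetic exactly from the simulated transwell amounts:

```
transport: Papp(AB) 5.3, Papp(BA) 21.5 nm/s; efflux ratio 4.1 (verapamil 1.7)
active efflux: True; P-gp substrate: True
```

(an efflux ratio above 2 indicates active efflux; its drop under the P-gp
inhibitor verapamil marks the compound as a P-gp substrate). The
trajectory stage finds the hydration shell the generator placed around the
ligand and the mean first-shell water count:

```
ligand-O_water RDF peaks at 2.55 A (g = 9.4) -- the first hydration shell
waters within 5 A of the ligand: 48.5 +- 4.4 per frame
```

A CLI mirrors the common steps, e.g.
`orcakit simulate plate --seed 7 --sigma 20 --out plate.csv` followed by
`orcakit ac50 plate.csv --out ac50.csv`.

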