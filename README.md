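# kgsdl

A desk-scale, fully simulated re-implementation of a knowledge-graph framework
for distributed self-driving laboratories. A scientist's goal request (objective
thresholds, search-space bounds, an experiment allowance, participating labs)
triggers autonomous design–make–test–analyse cycles executed by software agents
over a shared triple store. The physical flow-chemistry rigs are replaced by a
seeded plug-flow-reactor simulator of the base-catalysed aldol condensation
(benzaldehyde + acetone → benzylideneacetone) with an HPLC chromatogram
synthesiser, so collaborative multi-lab closed-loop cost–yield optimisation with
full provenance can be run and verified without hardware.

## What is inside

| Module | Role |
| --- | --- |
| `kgsdl.kg_store` | In-memory triple store, Turtle subset reader/writer, logical clock, domain vocabulary and typed views |
| `kgsdl.derivation` | Knowledge-graph-native workflow engine: derivations with typed inputs/outputs, statuses, round-robin agent polling, deadlock detection |
| `kgsdl.goals` | Goal request translation, per-lab iteration spawning, DMTA chain wiring, progress evaluation (continue / goals met / resources exhausted) |
| `kgsdl.doe` | DoE agent: Latin-hypercube start, then Thompson-sampling multi-objective Bayesian optimisation (GP surrogates, spectral posterior samples, NSGA-II, hypervolume-improvement selection) |
| `kgsdl.scheduler` | Digital twins of rigs and HPLC units: feasibility checks, molar-equivalents → pump-flow translation, stock depletion, equipment state, control-condition onboarding gate |
| `kgsdl.physsim` | Seeded isothermal PFR kinetics (vectorised RK4), chromatogram synthesis with injectable fault modes (internal-standard peak shift, product peak shift) |
| `kgsdl.postproc` | Internal-standard quantification, run material cost, E-factor, space-time yield, abnormal-result flagging |
| `kgsdl.campaign` | Configuration (pydantic + YAML), end-to-end orchestration, lineage queries, CSV/Turtle export |

The kinetic parameters, prices, retention windows and equipment limits are
declared fixtures chosen to reproduce the documented qualitative behaviour
(yield rises with temperature, is unimodal in acetone equivalents, depends
weakly on residence time; cost is exactly linear in the molar equivalents);
they are not a fitted model of the real chemistry.

## CLI

```bash
kgsdl validate                                   # check the built-in config
kgsdl run --seed 42 --out out/                   # run the default 2-lab campaign
kgsdl run --config campaign.yaml --seed 42 --out out/
kgsdl lineage --provenance out/provenance.ttl --experiment <IRI>
kgsdl replay --config campaign.yaml --seed 42 --out out/   # byte-identity check
```

`run` writes `results.csv` (one row per run: condition, lab, yield, cost,
E-factor, STY, abnormal flag, hypervolume trace, decision), `events.csv`
(the derivation event log) and `provenance.ttl` (the full campaign graph in
Turtle). Identical config + seed produce byte-identical outputs.

A campaign YAML mirrors `kgsdl.campaign.CampaignConfig`; start from
`python -c "import yaml, kgsdl; print(yaml.safe_dump(kgsdl.default_config().model_dump()))"`.

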