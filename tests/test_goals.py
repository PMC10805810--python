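import pytest

from kgsdl.campaign import run_campaign
from kgsdl.derivation import (DerivationEngine, DerivationStatus, TaskType)
from kgsdl.goals import (Direction, Goal, GoalRequestError, Restriction,
                         Verdict, evaluate_progress, parse_goal_request,
                         rogi_plan_iteration, spawn_goal_iterations)
from kgsdl.kg_store import (C, ExperimentStatus, Graph, Iri, IriMinter, KG, P,
                            PerformanceIndicator, RDF_TYPE, ReactionCondition,
                            ReactionExperiment, write_experiment)
from tests.conftest import make_config


def graph_with_labs(*names):
    g = Graph()
    for n in names:
        g.add(Iri(KG + "Lab/" + n), RDF_TYPE, C.Lab)
    return g


def request(labs=("a", "b"), allowance=65, **overrides):
    cfg = {
        "objectives": [
            {"objective": "yield", "direction": "maximise", "threshold": 90.0},
            {"objective": "run_material_cost", "direction": "minimise",
             "threshold": 3.0}],
        "search_space": {"equiv_acetone": (5.0, 50.0), "equiv_naoh": (0.05, 0.5),
                         "residence_time": (2.0, 10.0), "temperature": (30.0, 70.0)},
        "labs": [Iri(KG + "Lab/" + n) for n in labs],
        "cycle_allowance": allowance,
        "deadline": 10_000,
    }
    cfg.update(overrides)
    return cfg


class TestParseGoalRequest:
    def test_two_objective_two_lab_request(self):
        g = graph_with_labs("a", "b")
        gs = parse_goal_request(g, IriMinter(0), request())
        assert len(gs.goals) == 2
        assert len(g.query(gs.iri, P.hasGoal, None)) == 2
        assert len(g.query(gs.iri, P.hasLab, None)) == 2
        assert gs.restriction.cycle_allowance == 65

    def test_single_objective_degenerate_but_legal(self):
        g = graph_with_labs("a")
        gs = parse_goal_request(g, IriMinter(0), request(
            labs=("a",), objectives=[{"objective": "yield", "threshold": 90.0}]))
        assert len(gs.goals) == 1
        assert gs.goals[0].direction is Direction.maximise  # default

    def test_equal_bounds_rejected(self):
        g = graph_with_labs("a")
        bad = request(labs=("a",))
        bad["search_space"]["temperature"] = (50.0, 50.0)
        with pytest.raises(ValueError, match="degenerate"):
            parse_goal_request(g, IriMinter(0), bad)

    def test_missing_fields_listed(self):
        g = graph_with_labs("a")
        with pytest.raises(GoalRequestError, match="objectives"):
            parse_goal_request(g, IriMinter(0), {"labs": []})

    def test_unknown_lab_rejected(self):
        g = graph_with_labs("a")
        with pytest.raises(GoalRequestError, match="unknown lab"):
            parse_goal_request(g, IriMinter(0), request(labs=("a", "ghost")))


class TestSpawnGoalIterations:
    def _engine(self, g):
        engine = DerivationEngine(g, IriMinter(1))
        engine.register_agent(Iri(KG + "Agent/rogi"), TaskType.GoalIteration,
                              lambda e, d: None)
        return engine

    def test_one_derivation_per_lab(self):
        g = graph_with_labs("a", "b")
        gs = parse_goal_request(g, IriMinter(0), request())
        derivs = spawn_goal_iterations(self._engine(g), gs)
        assert len(derivs) == 2

    def test_single_lab(self):
        g = graph_with_labs("a")
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        assert len(spawn_goal_iterations(self._engine(g), gs)) == 1

    def test_removed_lab_not_spawned(self):
        g = graph_with_labs("a", "b")
        gs = parse_goal_request(g, IriMinter(0), request())
        gs.labs = gs.labs[:1]  # hardware removed mid-campaign
        assert len(spawn_goal_iterations(self._engine(g), gs)) == 1

    def test_no_rogi_agent_errors(self):
        g = graph_with_labs("a")
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        engine = DerivationEngine(g, IriMinter(1))
        with pytest.raises(LookupError):
            spawn_goal_iterations(engine, gs)


class TestRogiPlanIteration:
    def test_chain_structure(self):
        g = graph_with_labs("a")
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        engine = DerivationEngine(g, IriMinter(1))
        for tt in TaskType:
            engine.register_agent(Iri(KG + f"Agent/{tt.value}"), tt,
                                  lambda e, d: None)
        iteration = Iri(KG + "GoalIteration/1")
        chain = rogi_plan_iteration(engine, gs, gs.labs[0], iteration)
        assert set(chain) == {"doe", "schedule", "execution", "analysis",
                              "evaluation"}
        # placeholder wiring: each stage consumes the previous stage's output
        assert chain["schedule"].inputs == [chain["doe"].outputs[0]]
        assert chain["execution"].inputs == [chain["schedule"].outputs[0]]
        assert chain["analysis"].inputs == [chain["execution"].outputs[0]]
        assert chain["analysis"].outputs[0] in chain["evaluation"].inputs

    def test_missing_agent_raises_lookup(self):
        g = graph_with_labs("a")
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        engine = DerivationEngine(g, IriMinter(1))
        engine.register_agent(Iri(KG + "Agent/doe"), TaskType.DoE,
                              lambda e, d: None)
        with pytest.raises(LookupError, match="Schedule"):
            rogi_plan_iteration(engine, gs, gs.labs[0],
                                Iri(KG + "GoalIteration/1"))

    def test_stage_completion_order_in_campaign(self):
        cfg = make_config(allowance=2, labs=("cambridge",))
        from kgsdl.campaign import run_campaign
        res = run_campaign(cfg)
        stage_of = {}
        for d in res.engine.derivations.values():
            stage_of[d.iri] = d.task_type
        order = [stage_of[e.derivation] for e in res.engine.events
                 if e.transition.endswith("->Finished")]
        expected_cycle = [TaskType.GoalIteration, TaskType.DoE, TaskType.Schedule,
                          TaskType.Execution, TaskType.Analysis,
                          TaskType.ProgressEvaluation]
        assert order[:6] == expected_cycle


class TestEvaluateProgress:
    def _graph_with_experiment(self, yield_pct, cost):
        g = graph_with_labs("a")
        exp = ReactionExperiment(
            iri=Iri(KG + "ReactionExperiment/e1"),
            condition=ReactionCondition(10, 0.1, 5, 50),
            status=ExperimentStatus.Analysed, assigned_lab=Iri(KG + "Lab/a"),
            assigned_equipment=Iri(KG + "Lab/a/rig"),
            indicators=PerformanceIndicator(yield_pct, cost))
        write_experiment(g, exp)
        return g

    def test_goals_met(self):
        g = self._graph_with_experiment(95.0, 2.5)
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        decision = evaluate_progress(g, gs, executed=1, remaining_allowance=10,
                                     tick=g.clock, minter=IriMinter(2))
        assert decision.verdict is Verdict.StopGoalsMet

    def test_allowance_exhausted_overrides_pareto(self):
        g = self._graph_with_experiment(50.0, 4.0)
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        decision = evaluate_progress(g, gs, executed=65, remaining_allowance=0,
                                     tick=g.clock, minter=IriMinter(2))
        assert decision.verdict is Verdict.StopResourcesExhausted

    def test_deadline_exceeded(self):
        g = self._graph_with_experiment(50.0, 4.0)
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        decision = evaluate_progress(g, gs, executed=1, remaining_allowance=10,
                                     tick=20_000, minter=IriMinter(2))
        assert decision.verdict is Verdict.StopResourcesExhausted
        assert "deadline" in decision.rationale

    def test_continue_when_unmet_and_resourced(self):
        g = self._graph_with_experiment(50.0, 4.0)
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        decision = evaluate_progress(g, gs, executed=1, remaining_allowance=10,
                                     tick=g.clock, minter=IriMinter(2))
        assert decision.verdict is Verdict.Continue

    def test_decision_written_to_graph(self):
        g = self._graph_with_experiment(50.0, 4.0)
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        evaluate_progress(g, gs, executed=1, remaining_allowance=10,
                          tick=g.clock, minter=IriMinter(2))
        assert len(g.query(gs.iri, P.hasDecision, None)) == 1

    def test_joint_threshold_semantics(self):
        # one point meets yield only, another cost only -> goals NOT met
        g = graph_with_labs("a")
        for i, (y, c) in enumerate([(95.0, 4.0), (50.0, 2.0)]):
            exp = ReactionExperiment(
                iri=Iri(KG + f"ReactionExperiment/e{i}"),
                condition=ReactionCondition(10, 0.1, 5, 50),
                status=ExperimentStatus.Analysed, assigned_lab=Iri(KG + "Lab/a"),
                assigned_equipment=Iri(KG + "Lab/a/rig"),
                indicators=PerformanceIndicator(y, c))
            write_experiment(g, exp)
        gs = parse_goal_request(g, IriMinter(0), request(labs=("a",)))
        decision = evaluate_progress(g, gs, executed=2, remaining_allowance=10,
                                     tick=g.clock, minter=IriMinter(2))
        assert decision.verdict is Verdict.Continue


class TestCampaignIterationAccounting:
    def test_derivation_count_equals_labs_times_iterations(self):
        cfg = make_config(allowance=6, labs=("cambridge", "singapore"))
        res = run_campaign(cfg)
        iters = [d for d in res.engine.derivations.values()
                 if d.task_type is TaskType.GoalIteration]
        assert len(iters) == 6  # 2 labs x 3 iterations each
        assert res.executed == 6

    def test_goal_types(self):
        with pytest.raises(ValueError, match="unknown objective"):
            Goal("purity", Direction.maximise, 1.0)
        with pytest.raises(ValueError):
            Goal("yield", Direction.maximise, float("inf"))
        with pytest.raises(ValueError):
            Restriction(cycle_allowance=-1, deadline=10)
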