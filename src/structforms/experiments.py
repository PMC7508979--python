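"""Simulation experiments: basis-set inference versus associative baselines.

An experiment simulates an agent observing an incomplete graph over learning
blocks — pair presentations or random walks sampled from the observed graph —
and probes each learning model after every block.  Distance-comparison
questions use node triples whose answer is determined by the complete graph
but tied on the observed graph, so above-chance accuracy requires inferring
the never-observed links.  The structural agent answers through the inferred
abstract distance matrix; the baselines answer through successor-occupancy
estimates learnt from the same observations.  On community graphs the
structural agent is additionally scored on identifying the connecting nodes
through its emission estimate.

Per-simulation accuracies are compared with chance (0.5) by a one-tailed
one-sample t-test.  Simulations are independently seeded by spawning a seed
sequence, so results are reproducible and per-simulation streams do not
interact; within a simulation, every model sees identical observations and
identical questions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import basis as basis_mod
from . import distances as dist_mod
from . import graphs as graph_mod
from . import sr as sr_mod
from .inference import Candidate, EMOptions, infer_structure

__all__ = [
    "VARIANTS",
    "ExperimentConfig",
    "ExperimentResult",
    "ChanceComparison",
    "run_experiment",
    "compare_to_chance",
    "load_config",
    "fig4_config",
    "fig6a_config",
    "reproduce_fig4",
    "reproduce_fig6a",
]

#: Learning models probed by an experiment.  ``basis`` is the structural
#: agent; ``DA`` answers by discounted occupancy under row-normalized
#: transition counts, which makes it identical to ``SR-A`` (the closed-form
#: SR of the same counts) — both are kept so results tables carry the full
#: five-model layout; ``SR-online`` is the TD-learnt SR; ``SRreg`` its
#: symmetrized, spectrally regularized version.
VARIANTS = ("basis", "DA", "SR-online", "SR-A", "SRreg")

CHANCE_LEVEL = 0.5


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun an experiment deterministically."""

    name: str
    form: str  # generative form: "hexagonal" | "community"
    shape: tuple[int, int]
    seed: int
    omitted_edges: tuple[tuple[int, int], ...] = ()
    mode: str = "pairs"  # per-block observations: "pairs" | "walk"
    n_blocks: int = 7
    obs_per_block: int = 150  # pairs (pairs mode) or walk steps (walk mode)
    questions_per_block: int = 40
    inference_only: bool = True  # questions tied on the observed graph
    resample_questions: bool = True  # False: one frozen set per simulation
    n_sims: int = 10
    variants: tuple[str, ...] = VARIANTS
    candidate_forms: tuple[str, ...] = ("hexagonal", "community")
    gamma: float = sr_mod.DEFAULT_GAMMA
    alpha: float = sr_mod.DEFAULT_ALPHA
    n_components: int = sr_mod.DEFAULT_N_COMPONENTS
    em_restarts_first: int = 6  # random EM inits on the first block
    em_restarts_later: int = 3  # later blocks also warm-start from the previous fit
    em_screen_iters: int = 30
    em_finalists: int = 2
    em_max_iter: int = 300
    em_tol: float = 1e-6

    def __post_init__(self):
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")
        if self.mode not in ("pairs", "walk"):
            raise ValueError(f"unknown observation mode {self.mode!r}")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be in [0, 2**31)")

    def to_json(self) -> str:
        d = asdict(self)
        d["omitted_edges"] = [list(e) for e in self.omitted_edges]
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass(frozen=True)
class ExperimentResult:
    """Per-(simulation, block, variant) records plus the generating config.

    ``frame`` columns: sim, block, variant, n_questions, accuracy, map_form,
    map_size, fc, fIc.  Accuracy is NaN when no questions were asked; the
    map_* and connector columns are NaN for non-basis variants (and fc/fIc
    also when the MAP hypothesis has no connecting nodes).
    """

    config: ExperimentConfig
    frame: pd.DataFrame

    def per_sim_accuracy(self, variant: str) -> np.ndarray:
        """Mean accuracy per simulation, pooled over blocks, for one variant."""
        sub = self.frame[(self.frame["variant"] == variant)].dropna(subset=["accuracy"])
        if sub.empty:
            raise ValueError(f"no accuracy records for variant {variant!r}")
        return sub.groupby("sim")["accuracy"].mean().to_numpy()

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(out / f"{self.config.name}_results.csv", index=False)
        (out / f"{self.config.name}_config.json").write_text(self.config.to_json())
        import networkx
        import numba
        import scipy

        log = {
            "experiment": self.config.name,
            "master_seed": self.config.seed,
            "n_sims": self.config.n_sims,
            "versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "networkx": networkx.__version__,
                "numba": numba.__version__,
            },
        }
        (out / f"{self.config.name}_runlog.json").write_text(json.dumps(log, indent=1))


@dataclass(frozen=True)
class ChanceComparison:
    """One-tailed one-sample t-test of per-simulation accuracies vs chance."""

    variant: str
    mean_accuracy: float
    chance: float
    t_statistic: float
    p_value: float
    n: int
    alternative: str  # "greater" | "less"


def compare_to_chance(
    result_or_values,
    variant: str = "basis",
    chance: float = CHANCE_LEVEL,
    alternative: str = "greater",
) -> ChanceComparison:
    """t-test per-simulation mean accuracies against the chance level.

    Accepts an :class:`ExperimentResult` (per-sim accuracies are pooled over
    blocks for ``variant``) or a raw array of per-simulation accuracies.  If
    every simulation scored identically the t statistic is undefined; the
    p-value is then 0 or 1 by the sign of the (nonzero) difference from
    chance, and 0.5 at exact chance (t = 0, no evidence either way).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    if isinstance(result_or_values, ExperimentResult):
        values = result_or_values.per_sim_accuracy(variant)
    else:
        values = np.asarray(result_or_values, float)
    if values.size < 2:
        raise ValueError("need at least two simulations for a t-test")
    mean = float(values.mean())
    if np.ptp(values) == 0.0:
        diff = mean - chance
        if alternative == "less":
            diff = -diff
        t_stat = np.inf if diff > 0 else (-np.inf if diff < 0 else 0.0)
        p = 0.0 if diff > 0 else (1.0 if diff < 0 else 0.5)
    else:
        res = stats.ttest_1samp(values, chance, alternative=alternative)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return ChanceComparison(
        variant=variant,
        mean_accuracy=mean,
        chance=chance,
        t_statistic=t_stat,
        p_value=p,
        n=int(values.size),
        alternative=alternative,
    )


def load_config(path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML or JSON file.

    The file holds a flat mapping of config fields; YAML is a superset of
    JSON, so both formats parse with the same reader.
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping of fields")
    if "omitted_edges" in data:
        data["omitted_edges"] = tuple(tuple(int(x) for x in e) for e in data["omitted_edges"])
    for key in ("shape", "variants", "candidate_forms"):
        if key in data:
            data[key] = tuple(data[key])
    # YAML 1.1 reads scientific notation like "1e-06" as a string; coerce
    # scalars to the declared field types.
    for key, field in ExperimentConfig.__dataclass_fields__.items():
        if key in data and field.type == "float":
            data[key] = float(data[key])
        elif key in data and field.type == "int":
            data[key] = int(data[key])
    return ExperimentConfig(**data)


def _make_graphs(config: ExperimentConfig):
    if config.form == "hexagonal":
        full = graph_mod.make_hex_torus(*config.shape)
    elif config.form == "community":
        full = graph_mod.make_community_ring(*config.shape)
    else:
        raise ValueError(f"unknown generative form {config.form!r}")
    observed = (
        graph_mod.remove_edges(full, config.omitted_edges)
        if config.omitted_edges
        else full
    )
    return full, observed


def _connector_report(post, full):
    """fc/fIc for a MAP community hypothesis, or NaNs when not applicable."""
    if post.map_form != "community" or full.is_connecting is None:
        return np.nan, np.nan
    comm_size = full.shape[1]
    n_comm = post.map_size // comm_size
    conn_states = [c * comm_size + s for c in range(n_comm) for s in (0, 1)]
    true_syms = [i for i, c in enumerate(full.is_connecting) if c]
    rep = dist_mod.connecting_node_report(post.emission, conn_states, true_syms)
    return rep.fc, rep.fIc


def _run_simulation(sim: int, config: ExperimentConfig, sim_seed, full, observed, candidates):
    data_ss, question_ss, answer_ss, em_ss = sim_seed.spawn(4)
    data_rng = np.random.default_rng(data_ss)
    question_rng = np.random.default_rng(question_ss)
    em_rng = np.random.default_rng(em_ss)
    # One seed per (block, question): every variant answers a given question
    # with an identically seeded coin, so tie resolution is shared and
    # identical models produce identical answers.
    block_answer_ss = answer_ss.spawn(config.n_blocks)
    n = full.n_nodes
    obs = None
    questions = None
    warm: dict[tuple[str, int], np.ndarray] = {}
    td_model = sr_mod.SuccessorModel(
        m=np.zeros((n, n)), gamma=config.gamma, alpha=config.alpha, variant="td"
    )
    records = []
    for block in range(config.n_blocks):
        if config.mode == "pairs":
            seq = graph_mod.sample_pair_sequence(observed, config.obs_per_block, data_rng)
        else:
            seq = graph_mod.sample_random_walk(observed, config.obs_per_block, data_rng)
        obs = seq if obs is None else obs.concat(seq)
        if config.questions_per_block and (config.resample_questions or block == 0):
            questions = graph_mod.make_distance_questions(
                full, observed, config.questions_per_block,
                config.inference_only, question_rng,
            )
        elif not config.questions_per_block:
            questions = None

        answerers = {}
        extras: dict[str, dict] = {}
        if "basis" in config.variants:
            opts = EMOptions(
                restarts=config.em_restarts_first if block == 0 else config.em_restarts_later,
                tol=config.em_tol,
                max_iter=config.em_max_iter,
                screen_iters=config.em_screen_iters,
                finalists=config.em_finalists,
            )
            post = infer_structure(
                obs, candidates, opts=opts, rng=em_rng, n_symbols=n, warm_starts=warm
            )
            warm = {(s.form, s.size): s.emission.probs for s in post.scores}
            fc, fic = _connector_report(post, full)
            extras["basis"] = {
                "map_form": post.map_form, "map_size": post.map_size,
                "fc": fc, "fIc": fic,
            }
            if questions is not None:
                a_map = next(
                    c.transition for c in candidates
                    if (c.form, c.size) == (post.map_form, post.map_size)
                )
                # Symbols unseen so far keep their uniform state prior.
                d_tilde = dist_mod.observation_distances(
                    dist_mod.invert_emission(post.emission, unseen="uniform"),
                    dist_mod.abstract_distances(a_map),
                )
                answerers["basis"] = lambda q, rng: dist_mod.answer_closer_question(
                    d_tilde, q.option_a, q.option_b, q.target, rng
                )
        needs_td = {"SR-online", "SRreg"} & set(config.variants)
        if needs_td:
            td_model = sr_mod.td_sr_learn(td_model, seq, alpha=config.alpha)
            td_sym = sr_mod.symmetrize(td_model)
            if "SR-online" in config.variants:
                answerers["SR-online"] = lambda q, rng: sr_mod.sr_answer_question(
                    td_sym, q.option_a, q.option_b, q.target, rng
                )
            if "SRreg" in config.variants:
                td_reg = sr_mod.spectral_regularize(td_sym, config.n_components)
                answerers["SRreg"] = lambda q, rng: sr_mod.sr_answer_question(
                    td_reg, q.option_a, q.option_b, q.target, rng
                )
        if {"DA", "SR-A"} & set(config.variants):
            counts_sr = sr_mod.sr_closed_form(
                sr_mod.estimate_transition_counts(obs, n_states=n), config.gamma
            )
            for name in ("DA", "SR-A"):
                if name in config.variants:
                    answerers[name] = lambda q, rng: sr_mod.sr_answer_question(
                        counts_sr, q.option_a, q.option_b, q.target, rng
                    )

        question_seeds = (
            block_answer_ss[block].spawn(len(questions)) if questions is not None else []
        )
        for variant in config.variants:
            accuracy = np.nan
            if questions is not None:
                decide = answerers[variant]
                accuracy = float(
                    np.mean(
                        [
                            decide(q, np.random.default_rng(s)) == q.answer
                            for q, s in zip(questions, question_seeds)
                        ]
                    )
                )
            extra = extras.get(variant, {})
            records.append(
                {
                    "sim": sim,
                    "block": block,
                    "variant": variant,
                    "k": obs.n_observations,  # cumulative observation count
                    "n_questions": len(questions) if questions is not None else 0,
                    "accuracy": accuracy,
                    "map_form": extra.get("map_form", None),
                    "map_size": extra.get("map_size", np.nan),
                    "fc": extra.get("fc", np.nan),
                    "fIc": extra.get("fIc", np.nan),
                }
            )
    return records


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run all simulations of an experiment and collect per-block records.

    Every simulation draws its random streams from an independently spawned
    seed sequence; within a simulation all variants share the observations
    and question sets, and observations accumulate over blocks.
    """
    full, observed = _make_graphs(config)
    candidates = [
        Candidate(f, s, t)
        for f, s, t in basis_mod.candidate_transitions(forms=config.candidate_forms)
    ]
    sim_seeds = np.random.SeedSequence(config.seed).spawn(config.n_sims)
    records = []
    for sim, sim_seed in enumerate(sim_seeds):
        try:
            records.extend(
                _run_simulation(sim, config, sim_seed, full, observed, candidates)
            )
        except Exception as exc:
            if hasattr(exc, "add_note"):
                exc.add_note(f"while running simulation {sim} of {config.name!r}")
            raise
    return ExperimentResult(config=config, frame=pd.DataFrame.from_records(records))


def fig4_config(seed: int, n_sims: int = 10, **overrides) -> ExperimentConfig:
    """Missing-link inference on the 36-node hexagonal graph.

    Seven blocks of 150 adjacent-pair presentations from the observed graph
    (eight key links removed), 40 tied distance questions per block, all five
    models, ten simulations.
    """
    base = dict(
        name="fig4",
        form="hexagonal",
        shape=(6, 6),
        seed=seed,
        omitted_edges=tuple(sorted(graph_mod.FIXTURE_HEX_OMITTED_EDGES)),
        mode="pairs",
        n_blocks=7,
        obs_per_block=150,
        questions_per_block=40,
        inference_only=True,
        n_sims=n_sims,
        variants=VARIANTS,
        candidate_forms=("hexagonal", "community"),
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def fig6a_config(seed: int, n_sims: int = 20, **overrides) -> ExperimentConfig:
    """Connecting-node identification on the 35-node community graph.

    Seven blocks of 180 random-walk steps on the complete graph, no distance
    questions; the structural agent (community-form prior) is scored per
    block on MAP size and on connector identification (fc vs fIc), twenty
    simulations.
    """
    base = dict(
        name="fig6a",
        form="community",
        shape=(5, 7),
        seed=seed,
        omitted_edges=(),
        mode="walk",
        n_blocks=7,
        obs_per_block=180,
        questions_per_block=0,
        inference_only=True,
        n_sims=n_sims,
        variants=("basis",),
        candidate_forms=("community",),
        em_restarts_first=20,
        em_restarts_later=10,
        em_screen_iters=40,
        em_finalists=3,
        em_max_iter=400,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def reproduce_fig4(seed: int, out_dir=None, n_sims: int = 10, **overrides):
    """Run the hexagonal missing-link experiment and test accuracies vs chance.

    Returns (result, {variant: ChanceComparison}); the structural agent and
    the regularized SR are tested one-tailed above chance, the unfiltered
    baselines one-tailed below.
    """
    result = run_experiment(fig4_config(seed, n_sims=n_sims, **overrides))
    tests = {}
    for variant in result.config.variants:
        alternative = "greater" if variant in ("basis", "SRreg") else "less"
        tests[variant] = compare_to_chance(result, variant, alternative=alternative)
    if out_dir is not None:
        result.save(out_dir)
        payload = {v: asdict(t) for v, t in tests.items()}
        (Path(out_dir) / "fig4_ttests.json").write_text(json.dumps(payload, indent=1))
    return result, tests


def reproduce_fig6a(seed: int, out_dir=None, n_sims: int = 20, **overrides):
    """Run the community connecting-node experiment.

    Returns (result, summary) where summary holds the modal inferred
    community count in the final block and the mean fc/fIc per block.
    """
    result = run_experiment(fig6a_config(seed, n_sims=n_sims, **overrides))
    frame = result.frame[result.frame["variant"] == "basis"]
    comm_size = result.config.shape[1]
    final = frame[frame["block"] == result.config.n_blocks - 1]
    modal_size = int(final["map_size"].mode().iloc[0])
    by_block = frame.groupby("block")[["fc", "fIc"]].mean()
    summary = {
        "modal_final_communities": modal_size // comm_size,
        "modal_final_size": modal_size,
        "mean_fc_by_block": [float(x) for x in by_block["fc"]],
        "mean_fIc_by_block": [float(x) for x in by_block["fIc"]],
        "final_fc_mean": float(final["fc"].mean()),
        "final_fIc_mean": float(final["fIc"].mean()),
    }
    if out_dir is not None:
        result.save(out_dir)
        (Path(out_dir) / "fig6a_summary.json").write_text(json.dumps(summary, indent=1))
    return result, summary
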