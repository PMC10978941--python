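"""Synthetic task trials, behaviour and Poisson spike counts.

Stands in for the recorded dataset: it emulates both behavioural tasks
(numerical operation and instructed), behavioural choices with a numerical
size effect, and a population of premotor cells whose planted selectivity
profiles -- arithmetic, hand and step preferences, with known temporal
windows and arithmetic-to-motor coding transitions -- provide ground truth
for every downstream analysis stage.

Rate model: each cell has a baseline rate (spikes/s) modulated
multiplicatively by factor effects inside their temporal windows,

    rate(bin) = max(0, baseline * (1 + sum_f gain_f * s_f(trial) * 1[bin in window_f]))

where ``s_f`` is +1 when the trial matches the cell's preferred level of
factor ``f`` (positive gain sign = preference for addition / right hand /
1 step / standard stimulus) and -1 otherwise. Counts per 100-ms bin are
Poisson(rate * 0.1 s). The SNARC-like coupling ties the sign of the
arithmetic effect to the sign of the hand effect under the
addition <-> right-hand convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import task as T
from .population import BinnedPopulation

FACTOR_POSITIVE = {
    "arithmetic": T.ADDITION,
    "hand": T.RIGHT,
    "step": 1,
    "stimulus_type": T.STANDARD,
}


@dataclass
class CellProfile:
    """Planted selectivity of one synthetic cell.

    ``effects`` maps factor name to ``(gain, (onset_ms, offset_ms))`` with the
    window expressed relative to preoperational-numerosity onset within the
    2400-ms concern period. ``instructed_responsive=False`` plants a
    comparison-process cell: its arithmetic effect appears in the numerical
    operation task only, so the instructed-task filter should reject it.
    """

    cell_id: int
    baseline_rate: float = 10.0
    effects: dict[str, tuple[float, tuple[float, float]]] = field(default_factory=dict)
    coupling: str = "none"  # "none" | "snarc"
    category: str = "unselective"
    instructed_responsive: bool = True

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.coupling == "snarc" and {"arithmetic", "hand"} <= set(self.effects):
            ga, gh = self.effects["arithmetic"][0], self.effects["hand"][0]
            if ga * gh < 0:
                raise ValueError("snarc coupling requires matching effect signs")


@dataclass
class PopulationSpec:
    """Composition of a synthetic population.

    ``fractions`` maps category names (see :data:`CATEGORY_WINDOWS`) to
    population fractions; the remainder is unselective. Effect magnitudes are
    ``gain`` (fractional rate modulation) with random preferred side per cell,
    except that arithmetic and hand signs agree in a ``snarc_fraction`` of the
    cells carrying both effects.
    """

    n_cells: int = 539
    fractions: dict[str, float] = field(default_factory=dict)
    gain: float = 0.5
    baseline_rate: float = 10.0
    snarc_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.fractions.values()) > 1 + 1e-9:
            raise ValueError("category fractions must sum to <= 1")


@dataclass
class BehaviorModel:
    """Choice/RT model producing the numerical size effect.

    Numerical-task choices are the nearest integer in [0, 6] to a draw from
    Normal(target, sigma(target)) with sigma(t) = a + b*t, so decision noise
    grows with target magnitude. Instructed-task choices step one unit in the
    instructed direction with a small lapse rate and occasionally overshoot
    by a second step (magnitude-independent spread: no size effect planted).
    Reaction times carry a
    congruency advantage for addition-by-right-hand / subtraction-by-left-hand
    responses (a SNARC-like behavioural signature).
    """

    sigma_intercept: float = 0.3
    sigma_slope: float = 0.12
    lapse: float = 0.05
    instructed_overshoot: float = 0.15
    rt_base_ms: float = 450.0
    rt_sd_ms: float = 60.0
    rt_congruency_advantage_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.sigma_intercept <= 0 or self.sigma_slope < 0:
            raise ValueError("need sigma_intercept > 0 and sigma_slope >= 0")

    def sigma(self, target: np.ndarray | float) -> np.ndarray | float:
        return self.sigma_intercept + self.sigma_slope * np.asarray(target, float)


# temporal windows (ms from preoperational onset) per planted category
CATEGORY_WINDOWS: dict[str, dict[str, tuple[float, float]]] = {
    "arith_pure": {"arithmetic": (100, 2400)},
    "arith_to_hand": {"arithmetic": (100, 700), "hand": (1700, 2200)},
    "arith_to_step": {"arithmetic": (100, 700), "step": (2100, 2400)},
    "arith_hand_sim": {"arithmetic": (100, 1700), "hand": (400, 2100)},
    "comparison_only": {"arithmetic": (100, 700)},
    "hand_only": {"hand": (100, 2400)},
    "step_only": {"step": (100, 2400)},
    "snarc_reuse": {"arithmetic": (100, 1700), "hand": (1700, 2400)},
    "uncoupled": {"arithmetic": (100, 1700), "hand": (1700, 2400)},
    "static_code": {"arithmetic": (0, 2400)},
    "unselective": {},
}

#: composition emulating the recorded population: 539 cells of which 125 are
#: arithmetic-selective (16 remain exclusively arithmetic through the
#: operation period, 51 transition to hand or step coding, 58 code hand
#: simultaneously from the preoperational period on), 72 reflect the
#: comparison process only, and 83 / 89 are hand- / step-related during the
#: preoperational period (the 58 simultaneous coders count among the 83).
PAPER_LIKE_FRACTIONS = {
    "arith_pure": 16 / 539,
    "arith_to_hand": 35 / 539,
    "arith_to_step": 16 / 539,
    "arith_hand_sim": 58 / 539,
    "comparison_only": 72 / 539,
    "hand_only": 25 / 539,
    "step_only": 89 / 539,
}

ARITH_SELECTIVE_CATEGORIES = {
    "arith_pure", "arith_to_hand", "arith_to_step", "arith_hand_sim",
    "snarc_reuse", "uncoupled", "static_code",
}

PRESETS = ("paper_like", "null", "snarc_reuse", "static_code", "uncoupled")


def _cell_rng(master_seed: int, cell_id: int) -> np.random.Generator:
    # stable per-cell stream: independent of population size or cell order
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(cell_id)]))


def make_population(spec: PopulationSpec) -> list[CellProfile]:
    """Instantiate cell profiles from a population spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    categories: list[str] = []
    for name, frac in spec.fractions.items():
        if name not in CATEGORY_WINDOWS:
            raise ValueError(f"unknown cell category {name!r}")
        categories += [name] * int(round(frac * spec.n_cells))
    categories += ["unselective"] * (spec.n_cells - len(categories))
    categories = categories[: spec.n_cells]

    profiles = []
    n_uncoupled_seen = 0
    for cell_id, cat in enumerate(categories):
        windows = CATEGORY_WINDOWS[cat]
        s_arith = 1 if rng.random() < 0.5 else -1
        if cat == "snarc_reuse":
            s_hand, coupling = s_arith, "snarc"
        elif cat == "uncoupled":
            # exact counterbalancing: cycle the four sign pairs so the
            # population-level arithmetic->hand transfer cancels by design
            s_arith, s_hand = [(1, 1), (1, -1), (-1, 1), (-1, -1)][n_uncoupled_seen % 4]
            n_uncoupled_seen += 1
            coupling = "none"
        elif "hand" in windows and "arithmetic" in windows and rng.random() < spec.snarc_fraction:
            s_hand, coupling = s_arith, "snarc"
        else:
            s_hand, coupling = (1 if rng.random() < 0.5 else -1), "none"
        s_step = 1 if rng.random() < 0.5 else -1
        signs = {"arithmetic": s_arith, "hand": s_hand, "step": s_step}
        effects = {f: (signs[f] * spec.gain, w) for f, w in windows.items()}
        profiles.append(
            CellProfile(
                cell_id=cell_id,
                baseline_rate=spec.baseline_rate,
                effects=effects,
                coupling=coupling,
                category=cat,
                instructed_responsive=cat != "comparison_only",
            )
        )
    return profiles


def ground_truth_table(profiles: list[CellProfile]) -> pd.DataFrame:
    """Planted per-cell truth used by recovery tests."""
    rows = []
    for p in profiles:
        gains = {f: p.effects.get(f, (0.0, None))[0] for f in ("arithmetic", "hand", "step")}
        has_arith = gains["arithmetic"] != 0
        preop_end = 700
        rows.append({
            "cell_id": p.cell_id,
            "category": p.category,
            "baseline_rate": p.baseline_rate,
            "gain_arithmetic": gains["arithmetic"],
            "gain_hand": gains["hand"],
            "gain_step": gains["step"],
            "snarc": p.coupling == "snarc",
            "arithmetic_related": has_arith
            and p.effects["arithmetic"][1][0] < preop_end,
            "arithmetic_selective": p.category in ARITH_SELECTIVE_CATEGORIES,
            "hand_related": gains["hand"] != 0 and p.effects["hand"][1][0] < preop_end,
            "step_related": gains["step"] != 0 and p.effects["step"][1][0] < preop_end,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# trial generation

def generate_task_trials(
    task: str,
    n_trials: int,
    rule_block_length: int = 250,
    seed: int = 0,
    conditions: list[dict] | None = None,
    balanced: bool = False,
    p_control: float = 0.5,
    timeline: T.EventTimeline = T.DEFAULT_TIMELINE,
) -> pd.DataFrame:
    """Trial table skeleton: conditions, rules in blocks, stimulus sets.

    Conditions are drawn uniformly from :func:`pmdarith.task.enumerate_conditions`
    (or tiled evenly within each rule block when ``balanced``); the device rule
    alternates in blocks of ``rule_block_length`` trials; standard/control
    stimulus sets each appear in 50% of trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    conds = conditions if conditions is not None else T.enumerate_conditions(task)
    rule = np.where((np.arange(n_trials) // rule_block_length) % 2 == 0,
                    T.RULE1, T.RULE2)
    if balanced:
        idx = np.empty(n_trials, dtype=int)
        for r in (T.RULE1, T.RULE2):
            sel = np.flatnonzero(rule == r)
            tiled = np.resize(np.arange(len(conds)), len(sel))
            idx[sel] = rng.permutation(tiled)
    else:
        idx = rng.integers(0, len(conds), size=n_trials)
    events = timeline.event_times()
    df = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "task": task,
        "rule": rule,
        "target_numerosity": pd.array(
            [conds[i].get("target_numerosity") for i in idx], dtype="Int64"
        ),
        "preoperational_numerosity": [conds[i]["preoperational_numerosity"] for i in idx],
        "instruction": [conds[i].get("instruction", T.NO_INSTRUCTION) for i in idx],
        "stimulus_type": np.where(rng.random(n_trials) < p_control, T.CONTROL, T.STANDARD),
        "actions": "",
        "chosen_numerosity": 0,
        "correct": False,
        "reaction_time_ms": 0.0,
    })
    for name, t0 in events.items():
        df[f"t_{name}"] = t0
    return df


def _min_step_actions(preop: np.ndarray, chosen: np.ndarray, rule: np.ndarray) -> list[str]:
    steps = chosen - preop
    add_char = np.where(rule == T.RULE1, "L", "R")
    sub_char = np.where(rule == T.RULE1, "R", "L")
    return [
        (add_char[i] if s > 0 else sub_char[i]) * abs(int(s))
        for i, s in enumerate(steps)
    ]


def simulate_choices(
    trials: pd.DataFrame, model: BehaviorModel | None = None, seed: int = 0
) -> pd.DataFrame:
    """Fill chosen numerosity, minimum-step actions, outcome and RT."""
    model = model or BehaviorModel()
    rng = np.random.default_rng(seed)
    df = trials.copy()
    preop = df["preoperational_numerosity"].to_numpy(int)
    rule = df["rule"].to_numpy()
    numerical = (df["task"] == T.TASK_NUMERICAL).to_numpy()

    chosen = np.empty(len(df), dtype=int)
    if numerical.any():
        target = df.loc[numerical, "target_numerosity"].to_numpy(int)
        draw = rng.normal(target, model.sigma(target))
        chosen[numerical] = np.clip(np.rint(draw), 0, 6).astype(int)
    if (~numerical).any():
        instr = df.loc[~numerical, "instruction"].to_numpy()
        direction = np.where(instr == T.PLUS, 1, -1)
        flip = rng.random(direction.size) < model.lapse
        direction = np.where(flip, -direction, direction)
        magnitude = 1 + (rng.random(direction.size) < model.instructed_overshoot)
        chosen[~numerical] = np.clip(preop[~numerical] + direction * magnitude, 0, 6)

    df["chosen_numerosity"] = chosen
    df["actions"] = _min_step_actions(preop, chosen, rule)

    correct = np.empty(len(df), dtype=bool)
    correct[numerical] = chosen[numerical] == df.loc[
        numerical, "target_numerosity"
    ].to_numpy(int)
    instr_all = df["instruction"].to_numpy()
    correct[~numerical] = np.where(
        instr_all[~numerical] == T.PLUS,
        chosen[~numerical] > preop[~numerical],
        chosen[~numerical] < preop[~numerical],
    )
    df["correct"] = correct

    # RT: congruency advantage for addition-by-right / subtraction-by-left
    steps = chosen - preop
    executed_add = steps > 0
    first_left = df["actions"].str.startswith("L").to_numpy()
    hand_right = ~first_left & (np.abs(steps) > 0)
    congruent = (executed_add & hand_right) | (~executed_add & ~hand_right & (steps != 0))
    rt = model.rt_base_ms + rng.normal(0.0, model.rt_sd_ms, size=len(df))
    rt -= model.rt_congruency_advantage_ms * (congruent - 0.5)
    df["reaction_time_ms"] = np.maximum(rt, 50.0)
    return df


def balanced_decoding_trials(
    reps: int = 10, seed: int = 0, timeline: T.EventTimeline = T.DEFAULT_TIMELINE,
    rt_model: BehaviorModel | None = None,
) -> pd.DataFrame:
    """Correct minimum-step trials exactly balanced over the decoding design.

    ``reps`` trials for each of the 16 (target numerosity x arithmetic x hand)
    combinations -- the pseudopopulation inclusion design -- with the step
    drawn among feasible values and the rule chosen to realise the required
    hand. reps=10 gives the canonical 160-trial set.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for target in range(1, 5):
        for arith in (T.ADDITION, T.SUBTRACTION):
            for hand in (T.LEFT, T.RIGHT):
                rule = T.RULE1 if T.required_hand(arith, T.RULE1) == hand else T.RULE2
                feasible = [s for s in (1, 2)
                            if 0 <= (target - s if arith == T.ADDITION else target + s) <= 6]
                for _ in range(reps):
                    step = int(rng.choice(feasible))
                    preop = target - step if arith == T.ADDITION else target + step
                    char = "L" if hand == T.LEFT else "R"
                    rows.append((target, preop, rule, arith, hand, step, char * step))
    rng.shuffle(rows)
    events = timeline.event_times()
    df = pd.DataFrame(rows, columns=[
        "target_numerosity", "preoperational_numerosity", "rule",
        "_arith", "_hand", "_step", "actions",
    ])
    rt_model = rt_model or BehaviorModel()
    congruent = ((df["_arith"] == T.ADDITION) & (df["_hand"] == T.RIGHT)) | (
        (df["_arith"] == T.SUBTRACTION) & (df["_hand"] == T.LEFT)
    )
    rt = rt_model.rt_base_ms + rng.normal(0, rt_model.rt_sd_ms, len(df))
    rt -= rt_model.rt_congruency_advantage_ms * (congruent.to_numpy() - 0.5)
    out = pd.DataFrame({
        "trial_id": np.arange(len(df)),
        "task": T.TASK_NUMERICAL,
        "rule": df["rule"],
        "target_numerosity": pd.array(df["target_numerosity"], dtype="Int64"),
        "preoperational_numerosity": df["preoperational_numerosity"],
        "instruction": T.NO_INSTRUCTION,
        "stimulus_type": np.where(rng.random(len(df)) < 0.5, T.CONTROL, T.STANDARD),
        "actions": df["actions"],
        "chosen_numerosity": df["target_numerosity"],
        "correct": True,
        "reaction_time_ms": np.maximum(rt, 50.0),
    })
    for name, t0 in events.items():
        out[f"t_{name}"] = t0
    return T.label_trials(out)


# --------------------------------------------------------------------------
# spikes

def _factor_signs(trials: pd.DataFrame, factor: str,
                  instructed_responsive: bool = True) -> np.ndarray:
    """Per-trial preference sign (+1 preferred / -1 anti / 0 undefined)."""
    positive = FACTOR_POSITIVE[factor]
    if factor == "stimulus_type":
        vals = trials["stimulus_type"]
        s = np.where(vals == positive, 1.0, -1.0)
    else:
        vals = trials[factor]
        s = np.where(vals.isna(), 0.0, np.where(vals == positive, 1.0, -1.0))
    if factor == "arithmetic" and not instructed_responsive:
        s = np.where(trials["task"] == T.TASK_INSTRUCTED, 0.0, s)
    return s


def _window_mask(window: tuple[float, float], n_bins: int, bin_width: float) -> np.ndarray:
    starts = np.arange(n_bins) * bin_width
    onset, offset = window
    return (starts >= onset) & (starts < offset)


def simulate_cell_rates(
    profile: CellProfile,
    labels: T.OperationLabels,
    stimulus_type: str = T.STANDARD,
    timeline: T.EventTimeline = T.DEFAULT_TIMELINE,
) -> np.ndarray:
    """Rate (spikes/s) in each concern-period bin for one trial's labels."""
    if not labels.valid:
        raise ValueError("simulate_cell_rates requires valid labels")
    n_bins, bw = timeline.n_bins, timeline.bin_width_ms
    rate = np.full(n_bins, profile.baseline_rate)
    values = {"arithmetic": labels.arithmetic, "hand": labels.hand,
              "step": labels.step, "stimulus_type": stimulus_type}
    mod = np.zeros(n_bins)
    for f, (gain, window) in profile.effects.items():
        s = 1.0 if values[f] == FACTOR_POSITIVE[f] else -1.0
        mod += gain * s * _window_mask(window, n_bins, bw)
    return np.maximum(0.0, rate * (1.0 + mod))


def _rate_matrix(profile: CellProfile, trials: pd.DataFrame,
                 timeline: T.EventTimeline) -> np.ndarray:
    """(n_trials, n_bins) rates under the planted profile."""
    n_bins, bw = timeline.n_bins, timeline.bin_width_ms
    mod = np.zeros((len(trials), n_bins))
    for f, (gain, window) in profile.effects.items():
        s = _factor_signs(trials, f, profile.instructed_responsive)
        mod += gain * np.outer(s, _window_mask(window, n_bins, bw))
    return np.maximum(0.0, profile.baseline_rate * (1.0 + mod))


def simulate_population_spikes(
    spec_or_profiles: PopulationSpec | list[CellProfile],
    trials: pd.DataFrame,
    seed: int = 0,
    timeline: T.EventTimeline = T.DEFAULT_TIMELINE,
) -> tuple[BinnedPopulation, pd.DataFrame]:
    """Poisson spike counts for every cell over a labelled trial table.

    Returns the binned population and the planted ground-truth table. Counts
    are reproducible bit-exactly: each cell draws from its own stream derived
    from (seed, cell_id).
    """
    if isinstance(spec_or_profiles, PopulationSpec):
        profiles = make_population(spec_or_profiles)
    else:
        profiles = spec_or_profiles
    if "label_valid" not in trials.columns:
        raise ValueError("trials must be labelled (task.label_trials)")
    n_bins = timeline.n_bins
    dt = timeline.bin_width_ms / 1000.0
    counts = np.empty((len(profiles), len(trials), n_bins), dtype=np.int32)
    for i, prof in enumerate(profiles):
        rng = _cell_rng(seed, prof.cell_id)
        counts[i] = rng.poisson(_rate_matrix(prof, trials, timeline) * dt)
    pop = BinnedPopulation(
        counts, trials.reset_index(drop=True),
        cell_ids=np.array([p.cell_id for p in profiles]),
        bin_width_ms=timeline.bin_width_ms,
    )
    return pop, ground_truth_table(profiles)


# --------------------------------------------------------------------------
# fixture presets

@dataclass
class SyntheticDataset:
    """Everything one study-like synthetic session provides."""

    preset: str
    raw_trials: pd.DataFrame            # all simulated trials (behaviour stage)
    trials: pd.DataFrame                # correct minimum-step, labelled
    pop: BinnedPopulation               # numerical-task spike counts
    ground_truth: pd.DataFrame
    profiles: list[CellProfile]
    instructed_raw: pd.DataFrame | None = None
    instructed_trials: pd.DataFrame | None = None
    instructed_pop: BinnedPopulation | None = None

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {}
        T.write_trials(self.raw_trials, outdir / "trials_raw.csv",
                       meta={"preset": self.preset})
        files["trials_raw"] = "trials_raw.csv"
        T.write_trials(self.trials, outdir / "trials.csv")
        files["trials"] = "trials.csv"
        self.pop.save(outdir / "population.h5")
        files["population"] = "population.h5"
        self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        files["ground_truth"] = "ground_truth.csv"
        if self.instructed_pop is not None:
            T.write_trials(self.instructed_raw, outdir / "instructed_trials_raw.csv")
            self.instructed_pop.save(outdir / "instructed_population.h5")
            files["instructed_population"] = "instructed_population.h5"
        return files


def preset_spec(preset: str, n_cells: int | None = None, seed: int = 0) -> PopulationSpec:
    if preset == "paper_like":
        return PopulationSpec(n_cells=n_cells or 539,
                              fractions=dict(PAPER_LIKE_FRACTIONS), seed=seed)
    if preset == "null":
        return PopulationSpec(n_cells=n_cells or 200, fractions={}, seed=seed)
    if preset in ("snarc_reuse", "uncoupled", "static_code"):
        return PopulationSpec(n_cells=n_cells or 36, fractions={preset: 1.0}, seed=seed)
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def make_fixture_dataset(
    preset: str,
    seed: int = 0,
    n_cells: int | None = None,
    reps_per_condition: int | None = None,
    behavior: BehaviorModel | None = None,
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """Build a complete synthetic dataset for a named preset.

    paper_like  -- study-scale population (default 539 cells) with the full
                   category mix, behavioural size effect and both tasks;
    null        -- no planted effects (default 200 cells, 160 balanced
                   trials): every significance procedure should stay at its
                   nominal false-positive level;
    snarc_reuse -- an early arithmetic code re-expressed late as a
                   matched-sign hand code (the classifier-reuse asymmetry);
    uncoupled   -- same windows with exactly counterbalanced signs (control);
    static_code -- a constant arithmetic code across all 24 bins.
    """
    spec = preset_spec(preset, n_cells=n_cells, seed=seed)
    profiles = make_population(spec)
    behavior = behavior or BehaviorModel()
    ss = np.random.SeedSequence([seed, 0xA11CE])
    s_trials, s_choice, s_spk, s_itrials, s_ichoice, s_ispk = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)
    ]

    if preset in ("paper_like", "null"):
        reps = reps_per_condition or 20
        if preset == "null":
            raw = balanced_decoding_trials(reps=reps_per_condition or 10, seed=s_trials)
            labelled = raw
        else:
            n_conds = len(T.enumerate_conditions(T.TASK_NUMERICAL))
            n = 2 * reps * n_conds
            raw = generate_task_trials(T.TASK_NUMERICAL, n, rule_block_length=n // 4,
                                       seed=s_trials, balanced=True)
            raw = simulate_choices(raw, behavior, seed=s_choice)
            labelled = T.label_trials(T.filter_analysis_trials(raw))
        pop, truth = simulate_population_spikes(profiles, labelled, seed=s_spk)
        i_n = 2 * reps * 6
        iraw = generate_task_trials(T.TASK_INSTRUCTED, i_n, rule_block_length=i_n // 4,
                                    seed=s_itrials, balanced=True)
        iraw = simulate_choices(iraw, behavior, seed=s_ichoice)
        ilabelled = T.label_trials(T.filter_analysis_trials(iraw))
        ipop, _ = simulate_population_spikes(profiles, ilabelled, seed=s_ispk)
        ds = SyntheticDataset(preset, raw, labelled, pop, truth, profiles,
                              instructed_raw=iraw, instructed_trials=ilabelled,
                              instructed_pop=ipop)
    else:
        raw = balanced_decoding_trials(reps=reps_per_condition or 12, seed=s_trials)
        pop, truth = simulate_population_spikes(profiles, raw, seed=s_spk)
        ds = SyntheticDataset(preset, raw, raw, pop, truth, profiles)

    if outdir is not None:
        ds.write(outdir)
    return ds
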