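"""Closed-loop orchestration: training runs, success rates, test cases.

One simulation step closes the sensorimotor loop: scheduled world events
(re-placement every 1,000 steps, a random distractor step every 50), input
encoding (including the corollary discharge of the movement about to
happen), the network forward pass, population-vector decoding of the next
command, feedback-error RTRL (training phase only), application of the
pending command, and success bookkeeping — a step is a success when at
least one hand sits in the central 5x5-square block after moving.

Training success is estimated the way the classic cribside observations
were: a 10^4-step observation window every 5*10^5 steps (the 3 h / week
observation ratio 3/168 applied to the simulation clock), with consecutive
window ratios averaged pairwise.  Test-phase success uses frozen weights
over 10^5 steps (100 placements of 1,000 steps each) per saved checkpoint
and stimulus case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import world as gw
from .decoding import DecoderConfig, decode
from .encoding import TEST_CASES, TRAINING_CASE, CaseConfig, InputLayout, build_input
from .network import Network, NetworkConfig, init_network
from .rtrl import RTRLTrainer, TrainerConfig, motor_errors, network_error


@dataclass(frozen=True)
class RunConfig:
    """Schedules of a developmental run (all counts in time steps)."""

    total_steps: int = 55_000_000
    checkpoint_period: int = 1_000_000
    train_obs_interval: int = 500_000
    train_obs_window: int = 10_000
    reposition_period: int = 1_000
    other_move_period: int = 50
    test_window: int = 100_000
    test_placements: int = 100
    n_seeds: int = 10

    def __post_init__(self) -> None:
        if self.test_window != self.test_placements * self.reposition_period:
            raise ValueError(
                "test_window must equal test_placements * reposition_period "
                f"({self.test_window} != {self.test_placements} * "
                f"{self.reposition_period})"
            )
        if self.train_obs_window > self.train_obs_interval:
            raise ValueError("observation window cannot exceed its interval")


@dataclass
class SuccessSeries:
    """A success-rate time series (fractions in [0, 1]) at given steps."""

    steps: np.ndarray
    rates: np.ndarray
    phase: str
    case: str = ""

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.steps) != len(self.rates):
            raise ValueError("steps and rates must have equal length")
        if np.any(np.diff(self.steps) <= 0):
            raise ValueError("steps must be strictly increasing")
        if self.rates.size and (self.rates.min() < 0 or self.rates.max() > 1):
            raise ValueError("rates must lie in [0, 1]")


def paired_series(raw: SuccessSeries) -> SuccessSeries:
    """Average consecutive non-overlapping window ratios pairwise.

    Mirrors the two-score averaging of the cribside study ("the average of
    two scores taken during successive periods"); each point sits at the
    midpoint of its window pair.
    """
    n = len(raw.rates) // 2
    steps = (raw.steps[: 2 * n : 2] + raw.steps[1 : 2 * n : 2]) // 2
    rates = (raw.rates[: 2 * n : 2] + raw.rates[1 : 2 * n : 2]) / 2.0
    return SuccessSeries(steps, rates, raw.phase, raw.case)


def baseline_success_probability(geometry: gw.GridGeometry) -> float:
    """Analytic success rate of motionless, uniformly placed hands.

    With hands frozen where they land, a placement succeeds iff at least one
    of the two independent uniform positions falls in the central block:
    ``1 - (1 - n_center/n_area)^2`` (~0.210 for 25 of 225 squares).
    """
    p = geometry.block_size**2 / (geometry.area_width * geometry.area_height)
    return 1.0 - (1.0 - p) ** 2


class Simulation:
    """The closed loop for one case; steps the world/network/trainer jointly.

    ``rng`` drives world randomness only (placements and distractor steps);
    network initialization uses its own stream so that paired comparisons
    across cases see identical worlds.
    """

    def __init__(
        self,
        geometry: gw.GridGeometry,
        layout: InputLayout,
        network: Network,
        case: CaseConfig,
        run_config: RunConfig,
        rng: np.random.Generator,
        decoder: DecoderConfig = DecoderConfig(),
        trainer: RTRLTrainer | None = None,
    ):
        self.geometry = geometry
        self.layout = layout
        self.net = network
        self.case = case
        self.run_config = run_config
        self.rng = rng
        self.decoder = decoder
        self.trainer = trainer
        self.world = gw.init_world(geometry, case, rng)
        self.pending_cmd = gw.ZERO_COMMAND
        self._z = np.empty(network.n_pre)
        self._ebuf = np.zeros(8)
        self.last_errors: np.ndarray | None = None

    def step(self) -> bool:
        """Advance one time step; returns the post-move in-center flag."""
        w, g, case, rc = self.world, self.geometry, self.case, self.run_config
        t = w.t
        if gw.schedule_due(t, rc.reposition_period):
            gw.reposition(w, g, case, self.rng)
            if (
                self.trainer is not None
                and self.trainer.config.reset_sensitivities_on_reposition
            ):
                self.trainer.reset_sensitivities()
        elif gw.schedule_due(t, rc.other_move_period):
            gw.step_other(w, g, case, self.rng)

        # The pending command (decoded from the previous step's output) is
        # the movement happening this step; the corollary discharge
        # announces exactly that movement.
        build_input(w, self.pending_cmd, g, case, self.layout, self._z)
        # _z already holds the input segment; append recurrent state + bias.
        self._z[self.layout.total : -1] = self.net.hidden_prev
        self._z[-1] = 1.0
        h, y = self.net.forward_pre(self._z)
        new_cmd = decode(y, self.decoder)

        if self.trainer is not None:
            # Fast equivalent of motor_errors(perceived_block(...)): with
            # perceived positions quantized to block centers, the error
            # equations reduce to (1 - bcol, brow - 1) per axis (equality
            # with the cm-frame formulas is asserted in the test suite).
            blc, blr = g.block_index(w.left_hand)
            brc, brr = g.block_index(w.right_hand)
            e = self._ebuf
            e[0] = 1 - blc
            e[1] = blr - 1
            e[2] = blc - 1
            e[3] = 1 - blr
            e[4] = 1 - brc
            e[5] = brr - 1
            e[6] = brc - 1
            e[7] = 1 - brr
            self.last_errors = e
            self.trainer.step(self._z, h, y, e)

        gw.apply_moves(w, self.pending_cmd, g)
        self.pending_cmd = new_cmd
        return gw.in_center(w.left_hand, g) or gw.in_center(w.right_hand, g)

    def run(
        self,
        n_steps: int,
        record_positions: bool = False,
        record_hidden: bool = False,
    ) -> dict:
        """Run ``n_steps``; returns success flags and optional logs."""
        success = np.empty(n_steps, dtype=bool)
        pos = np.empty((n_steps, 4), dtype=np.int16) if record_positions else None
        hid = np.empty((n_steps, self.net.n_hidden)) if record_hidden else None
        for i in range(n_steps):
            success[i] = self.step()
            if pos is not None:
                pos[i, 0:2] = self.world.left_hand
                pos[i, 2:4] = self.world.right_hand
            if hid is not None:
                hid[i] = self.net.hidden
        out = {"success": success}
        if pos is not None:
            out["positions"] = pos
        if hid is not None:
            out["hidden"] = hid
        return out


def seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent random streams for one run.

    Separate world and network-init streams mean a change of network seed
    never changes the world's placement sequence (paired comparisons).
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2)
    return {
        "network": np.random.Generator(np.random.PCG64(children[0])),
        "world": np.random.Generator(np.random.PCG64(children[1])),
    }


@dataclass
class TrainResult:
    """Outcome of one training run (one weight-initialization seed)."""

    seed: int
    window_series: SuccessSeries  # raw per-window in-center ratios
    series: SuccessSeries  # pairwise-averaged training success rate
    checkpoints: dict[int, Network]  # step -> frozen copy of the network
    network: Network  # final state (same object the run used)
    positions: np.ndarray | None = None  # (T, 4) int16 when trajectory logged


def train(
    geometry: gw.GridGeometry,
    layout: InputLayout,
    net_config: NetworkConfig,
    run_config: RunConfig,
    trainer_config: TrainerConfig,
    seed: int,
    decoder: DecoderConfig = DecoderConfig(),
    case: CaseConfig = TRAINING_CASE,
    log_trajectory: bool = False,
    progress_callback=None,
) -> TrainResult:
    """One full training run with checkpointing and windowed success scoring.

    Weights are saved (as in-memory copies keyed by step, including step 0)
    every ``checkpoint_period`` steps.  In-center flags are scored inside
    ``train_obs_window``-long windows opened at every ``train_obs_interval``
    steps; the returned ``series`` averages consecutive window pairs.
    """
    streams = seed_streams(seed)
    net = init_network(streams["network"], layout.total, net_config, layout.cd)
    trainer = RTRLTrainer(net, trainer_config)
    sim = Simulation(
        geometry, layout, net, case, run_config, streams["world"], decoder, trainer
    )
    total = run_config.total_steps
    interval, window = run_config.train_obs_interval, run_config.train_obs_window
    checkpoints: dict[int, Network] = {0: net.copy()}
    ratios: list[float] = []
    window_steps: list[int] = []
    pos = np.empty((total, 4), dtype=np.int16) if log_trajectory else None
    in_window = 0
    hits = 0
    for t in range(total):
        success = sim.step()
        if pos is not None:
            pos[t, 0:2] = sim.world.left_hand
            pos[t, 2:4] = sim.world.right_hand
        if t % interval < window:
            hits += success
            in_window += 1
            if in_window == window:
                ratios.append(hits / window)
                window_steps.append(t - window + 1 + window // 2)
                hits = 0
                in_window = 0
        if (t + 1) % run_config.checkpoint_period == 0:
            checkpoints[t + 1] = net.copy()
            if progress_callback is not None:
                progress_callback(t + 1, ratios[-1] if ratios else float("nan"))
    raw = SuccessSeries(np.array(window_steps), np.array(ratios), "training")
    return TrainResult(
        seed=seed,
        window_series=raw,
        series=paired_series(raw),
        checkpoints=checkpoints,
        network=net,
        positions=pos,
    )


def servo_convergence(
    geometry: gw.GridGeometry,
    layout: InputLayout,
    net_config: NetworkConfig,
    trainer_config: TrainerConfig,
    seed: int,
    max_steps: int = 100_000,
    decoder: DecoderConfig = DecoderConfig(),
) -> int | None:
    """Frozen-world servo smoke test: steps until the error vanishes.

    With no distractor and no repositioning, online training must drive
    both hands into the central block (all motor errors zero, J = 0) from a
    random initialization.  Returns the first 1-based step at which J = 0,
    or None if it never happens within ``max_steps``.
    """
    case = CaseConfig("servo", n_others=0)
    # Schedules that never fire within the run: a frozen world.
    run_config = RunConfig(
        total_steps=max_steps,
        checkpoint_period=max_steps,
        train_obs_interval=max_steps,
        train_obs_window=1,
        reposition_period=max_steps + 1,
        other_move_period=max_steps + 1,
        test_window=max_steps + 1,
        test_placements=1,
        n_seeds=1,
    )
    streams = seed_streams(seed)
    net = init_network(streams["network"], layout.total, net_config, layout.cd)
    trainer = RTRLTrainer(net, trainer_config)
    sim = Simulation(
        geometry, layout, net, case, run_config, streams["world"], decoder, trainer
    )
    for t in range(max_steps):
        sim.step()
        if not sim.last_errors.any():
            return t + 1
    return None


def test_case_run(
    network: Network,
    case: CaseConfig | int,
    geometry: gw.GridGeometry,
    layout: InputLayout,
    run_config: RunConfig,
    world_seed: int,
    decoder: DecoderConfig = DecoderConfig(),
) -> float:
    """Success rate of frozen weights under one stimulus case.

    Runs ``test_window`` steps (``test_placements`` placements of
    ``reposition_period`` steps each) with learning disabled and the
    distractors kept inside the FOV.  The caller's network is not mutated
    (a copy runs); the world stream depends only on ``world_seed``, so all
    cases at a given seed see identical worlds.
    """
    if isinstance(case, int):
        if case not in TEST_CASES:
            raise KeyError(f"unknown test case id {case}")
        case = TEST_CASES[case]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(world_seed)))
    sim = Simulation(
        geometry, layout, network.copy(), case, run_config, rng, decoder, trainer=None
    )
    out = sim.run(run_config.test_window)
    return float(out["success"].mean())


def run_suite(
    results: list[TrainResult],
    geometry: gw.GridGeometry,
    layout: InputLayout,
    run_config: RunConfig,
    cases: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7),
    decoder: DecoderConfig = DecoderConfig(),
    checkpoint_steps: list[int] | None = None,
) -> pd.DataFrame:
    """Test every (seed, checkpoint, case) combination; long-format table.

    The world seed of a test run is derived from the training seed only, so
    the seven cases of one seed are a paired comparison.
    """
    rows = []
    for res in results:
        steps = checkpoint_steps or sorted(res.checkpoints)
        for step in steps:
            net = res.checkpoints[step]
            for case_id in cases:
                rate = test_case_run(
                    net, case_id, geometry, layout, run_config,
                    world_seed=(res.seed + 1) * 1_000_003, decoder=decoder,
                )
                rows.append(
                    {"seed": res.seed, "step": step, "case": case_id, "rate": rate}
                )
    return pd.DataFrame(rows)


def ensemble_average(table: pd.DataFrame) -> pd.DataFrame:
    """Mean success rate over seeds per (checkpoint step, case)."""
    return (
        table.groupby(["step", "case"], as_index=False)["rate"]
        .mean()
        .sort_values(["case", "step"], ignore_index=True)
    )
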