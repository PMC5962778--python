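"""HDF5 checkpoints: weights, masks, step counter, optional trainer state.

A checkpoint restores a bit-identical network (weights, mask, hidden state).
The trainer's sensitivity tensor is excluded by default (it is large); pass
``trainer`` to save it for exact-resume runs — a checkpoint without it can
still resume, but the first few updates after resuming differ slightly
from an uninterrupted run (flagged via the ``exact_resume`` attribute).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .network import Network, NetworkConfig
from .rtrl import RTRLTrainer, TrainerConfig

FORMAT_VERSION = 1


class CheckpointError(RuntimeError):
    """Missing, corrupt or incompatible checkpoint file."""


def save_checkpoint(
    network: Network,
    path: str | Path,
    step: int,
    rng: np.random.Generator | None = None,
    trainer: RTRLTrainer | None = None,
    config_hash: str = "",
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["step"] = step
        f.attrs["config_hash"] = config_hash
        f.attrs["n_in"] = network.n_in
        f.attrs["n_hidden"] = network.n_hidden
        f.attrs["n_agency"] = network.config.n_agency
        f.attrs["n_outputs"] = network.n_outputs
        f.attrs["init_scale"] = network.config.init_scale
        f.attrs["cd_start"] = network.cd_slice.start
        f.attrs["cd_stop"] = network.cd_slice.stop
        f.attrs["exact_resume"] = trainer is not None
        g = f.create_group("weights")
        g.create_dataset("W_h", data=network.W_h)
        g.create_dataset("W_out", data=network.W_out)
        g.create_dataset("b_out", data=network.b_out)
        f.create_dataset("mask", data=network.mask)
        f.create_dataset("hidden_prev", data=network.hidden_prev)
        if rng is not None:
            f.attrs["rng_state"] = json.dumps(
                rng.bit_generator.state, default=int
            )
        if trainer is not None:
            t = f.create_group("trainer")
            t.create_dataset("P", data=trainer.P)
            t.create_dataset("grad_hid", data=trainer.grad_hid)
            t.create_dataset("grad_out", data=trainer.grad_out)
            t.create_dataset("grad_b_out", data=trainer.grad_b_out)
            t.attrs["steps_since_update"] = trainer.steps_since_update


def load_checkpoint(
    path: str | Path, trainer_config: TrainerConfig | None = None
) -> tuple[Network, dict]:
    """Rebuild the network (and optionally trainer) from a checkpoint.

    Returns ``(network, meta)``; ``meta`` holds ``step``, ``config_hash``,
    ``exact_resume``, the restored ``rng`` (or None) and, when the file
    contains trainer state and ``trainer_config`` is given, a ready
    ``trainer``.
    """
    path = Path(path)
    if not path.exists():
        raise CheckpointError(f"checkpoint not found: {path}")
    try:
        with h5py.File(path, "r") as f:
            if int(f.attrs["format_version"]) != FORMAT_VERSION:
                raise CheckpointError(
                    f"{path}: unsupported format version {f.attrs['format_version']}"
                )
            cfg = NetworkConfig(
                n_hidden=int(f.attrs["n_hidden"]),
                n_agency=int(f.attrs["n_agency"]),
                n_outputs=int(f.attrs["n_outputs"]),
                init_scale=float(f.attrs["init_scale"]),
            )
            cd_slice = slice(int(f.attrs["cd_start"]), int(f.attrs["cd_stop"]))
            net = Network(
                int(f.attrs["n_in"]), cfg, cd_slice, np.random.default_rng(0)
            )
            net.W_h[:] = f["weights/W_h"][()]
            net.W_out[:] = f["weights/W_out"][()]
            net.b_out[:] = f["weights/b_out"][()]
            net.mask[:] = f["mask"][()]
            net.hidden_prev[:] = f["hidden_prev"][()]
            meta = {
                "step": int(f.attrs["step"]),
                "config_hash": str(f.attrs["config_hash"]),
                "exact_resume": bool(f.attrs["exact_resume"]),
                "rng": None,
                "trainer": None,
            }
            if "rng_state" in f.attrs:
                rng = np.random.default_rng()
                rng.bit_generator.state = json.loads(str(f.attrs["rng_state"]))
                meta["rng"] = rng
            if "trainer" in f and trainer_config is not None:
                trainer = RTRLTrainer(net, trainer_config)
                trainer.P[:] = f["trainer/P"][()]
                trainer.grad_hid[:] = f["trainer/grad_hid"][()]
                trainer.grad_out[:] = f["trainer/grad_out"][()]
                trainer.grad_b_out[:] = f["trainer/grad_b_out"][()]
                trainer.steps_since_update = int(
                    f["trainer"].attrs["steps_since_update"]
                )
                meta["trainer"] = trainer
    except (OSError, KeyError) as exc:
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    return net, meta
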