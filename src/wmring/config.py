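"""Structured-text (TOML) task configuration.

Sections [prior], [tuning], [schedule], [noise] override the package
defaults, e.g.::

    [prior]
    sigma_s = 12.5

    [schedule]
    delay_ms = 800.0

    [noise]
    sigma_x = 0.2
    sigma_rec = 0.2
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from .task_env import EnvironmentPrior, EpochSchedule, NoiseConfig, TuningBank


def load_task_config(path):
    """Parse a TOML task config into (prior, bank, schedule, noise)."""
    data = tomllib.loads(Path(path).read_text())
    prior = EnvironmentPrior(**data.get("prior", {}))
    bank = TuningBank(**data.get("tuning", {}))
    schedule = EpochSchedule(**data.get("schedule", {}))
    noise = NoiseConfig(**data.get("noise", {}))
    return prior, bank, schedule, noise
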