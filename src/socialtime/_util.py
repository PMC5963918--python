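"""Internal helpers: error types, seeding, shared trial-table schema."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = [
    "SocialtimeError",
    "ConfigurationError",
    "ValidationError",
    "InsufficientDataError",
    "DegenerateSlopeError",
    "TrialParseError",
    "substream",
    "TRIAL_COLUMNS",
]


class SocialtimeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SocialtimeError):
    """Invalid population/design/run configuration."""


class ValidationError(SocialtimeError):
    """Input data violates a precondition (mixed observers, length mismatch, ...)."""


class InsufficientDataError(SocialtimeError):
    """Too few informative stimulus levels to attempt a psychometric fit."""


class DegenerateSlopeError(SocialtimeError):
    """The slope parameter omega is zero; the sigmoid is undefined."""


class TrialParseError(SocialtimeError):
    """A trial CSV failed schema validation; the message names offending rows."""


# Canonical column order of the trial-level table written/read throughout.
TRIAL_COLUMNS = (
    "observer_id",
    "experiment_id",
    "condition",
    "block",
    "delta_ms",
    "standard_is_communicative",
    "communicative_first",
    "chose_communicative_longer",
)


def derive_seed(seed: int, *keys) -> int:
    """Derive a child integer seed (< 2**31) from a root seed and string keys."""
    spawn_key = tuple(zlib.crc32(str(k).encode("utf-8")) for k in keys)
    ss = np.random.SeedSequence(int(seed), spawn_key=spawn_key)
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, reproducible random substream derived from a single root seed.

    Every source of randomness in the package draws from a substream keyed by
    what it is for (``substream(seed, "trials", observer_id, condition)``), so
    re-running any stage in isolation reproduces its output exactly.  Keys are
    hashed with CRC-32, which is stable across platforms and sessions.
    """
    spawn_key = tuple(zlib.crc32(str(k).encode("utf-8")) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn_key))
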