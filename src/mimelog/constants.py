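"""Physiological constants of the pituitary-thyroid feedback model.

The structural parameters of an individual (S, phi, G_T) sit on top of a set
of population-level constants describing hormone distribution, elimination
and plasma protein binding. The defaults shipped in ``data/spina_defaults.cfg``
come from the SPINA model literature; every operation in this package takes
the constants explicitly so no result depends on a hidden global.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from importlib import resources

from .config import read_config, parse_config_text

__all__ = ["ModelConstants", "DEFAULT_CONSTANTS", "load_constants"]


@dataclass(frozen=True)
class ModelConstants:
    """Immutable physiological constants; every field strictly positive.

    Units: ``d_t`` mIU/L; ``alpha_t``, ``alpha_31`` 1/L; ``beta_t``,
    ``beta_31`` 1/s; ``k41``, ``k42``, ``k30`` L/mol; ``tbg``, ``ttr`` mol/L;
    ``k_m1`` nmol/L.
    """

    d_t: float = 2.75
    alpha_t: float = 0.1
    beta_t: float = 1.1e-6
    k41: float = 2.0e10
    k42: float = 2.0e8
    tbg: float = 3.0e-7
    ttr: float = 4.5e-6
    alpha_31: float = 0.026
    beta_31: float = 8.0e-6
    k_m1: float = 500.0
    k30: float = 2.0e9

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            value = getattr(self, field.name)
            if not (isinstance(value, (int, float)) and value > 0):
                raise ValueError(
                    f"ModelConstants.{field.name} must be strictly positive, got {value!r}"
                )

    @property
    def t4_binding_factor(self) -> float:
        """1 + K41·[TBG] + K42·[TTR] — plasma protein binding correction for T4."""
        return 1.0 + self.k41 * self.tbg + self.k42 * self.ttr

    def replace(self, **overrides: float) -> "ModelConstants":
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def _from_mapping(mapping: dict) -> ModelConstants:
    known = {f.name for f in dataclasses.fields(ModelConstants)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown constant keys: {sorted(unknown)}; expected {sorted(known)}")
    return ModelConstants(**mapping)


def load_constants(path: str | os.PathLike | None = None) -> ModelConstants:
    """Load constants from a ``key = value`` file; ``None`` loads the bundled
    defaults. Keys missing from the file fall back to the defaults; unknown
    keys are rejected."""
    if path is None:
        text = resources.files("mimelog.data").joinpath("spina_defaults.cfg").read_text()
        return _from_mapping(parse_config_text(text))
    return _from_mapping(read_config(path))


DEFAULT_CONSTANTS = load_constants()
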