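"""Runtime configuration shared by the library and the CLI.

All tunables of the comparison pipeline live here with their defaults:
the autocorrelation sizes w = omega = 4, the deletion-weight constant
c_del = 0.6 and the entropy down-scaling factor 0.5 are the method's stated
defaults; the remaining values (score precision bits, pseudocount mass,
thickness-factor and z-reestimation parameters) are package choices
documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

__all__ = ["SearchConfig", "load_config_file"]


@dataclass(frozen=True)
class SearchConfig:
    # profile construction
    pseudocount_weight: float = 10.0
    seg_high: bool = True
    seg_low: bool = False
    seg_window: int = 12

    # pair score system
    c_bits: int = 5              # score precision: scores scaled by 2**c_bits
    c_bits_K: int = 2            # coarser lattice used for the K series
    kappa: float = 1.0           # entropy-threshold proportionality constant
    downscale_factor: float = 0.5
    expected_evalue: float = 1e-4  # pre-computed E-value per hit (threshold)

    # gap model
    w: int = 4
    omega: int = 4
    c_del: float = 0.6
    zeta: float = 1.0            # pass-1 widening: z1 = zeta / sqrt(H)
    x: float = 0.0               # pass-2: z2 = -y / (log E + x)
    y: float = 10.0
    z_max: float = 10.0
    u: float = 1.0               # thickness factor 1/(1+exp(-t*u+v))
    v: float = 2.0

    # statistics / reporting
    edge_correction: bool = False
    evalue_threshold: float = 10.0
    max_hits: int = 500
    seed: int = 0
    log_level: str = "info"

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")
        if self.w < 1 or self.omega < 1:
            raise ValueError("w and omega must be >= 1")

    def with_overrides(self, **kwargs) -> "SearchConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs) if kwargs else self


_BOOLS = {"true": True, "1": True, "yes": True,
          "false": False, "0": False, "no": False}


def load_config_file(path) -> SearchConfig:
    """Parse a ``key = value`` configuration file mirroring the CLI flags."""
    values: dict = {}
    types = {f.name: f.type for f in fields(SearchConfig)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key '{key}'")
            t = types[key]
            if t in ("bool", bool):
                values[key] = _BOOLS[raw.lower()]
            elif t in ("int", int):
                values[key] = int(raw)
            elif t in ("float", float):
                values[key] = float(raw)
            else:
                values[key] = raw
    return SearchConfig(**values)
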