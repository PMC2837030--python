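"""Serialized profile records and flat-file profile databases.

The profile format is a versioned plain-text format, one block per position
with a fixed field order; round-trips are lossless to the printed precision
(8 decimals, tested at 1e-6).  A profile database is an index header followed
by the concatenated profile records; the index carries the total number of
positions and, once computed, the reference statistical parameters of the
database's global score system.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .profile import Profile

__all__ = ["ProfileFormatError", "write_profile", "read_profile",
           "ProfileDatabase", "write_database", "read_database"]

FORMAT_VERSION = "1"
_MAGIC = "COMA PROFILE"
_DB_MAGIC = "COMA PROFILE DB"


class ProfileFormatError(ValueError):
    """Malformed or truncated profile file."""


def _floats(text: str) -> np.ndarray:
    return np.array(text.split(), dtype=float)


def _fmt(values) -> str:
    return " ".join(f"{v:.8f}" for v in np.atleast_1d(values))


def write_profile(profile: Profile, stream) -> None:
    close = False
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        stream = open(stream, "w")
        close = True
    try:
        w = stream.write
        w(f"{_MAGIC} v{FORMAT_VERSION}\n")
        w(f"name {profile.name}\n")
        w(f"length {profile.length}\n")
        w(f"table {profile.table_name}\n")
        w(f"lambda_ref {profile.lambda_ref:.10f}\n")
        w(f"source {profile.source}\n")
        w(f"build_params {profile.build_params}\n")
        for i in range(profile.length):
            w(f"pos {i} column {int(profile.columns[i])}\n")
            w("F " + _fmt(profile.obs_freq[i]) + "\n")
            w("G " + _fmt(profile.gap_freq[i]) + "\n")
            w("T " + _fmt(profile.target[i]) + "\n")
            w("S " + _fmt(profile.scores[i]) + "\n")
            w("E " + _fmt([profile.eff_seqs[i], profile.del_prob[i],
                           profile.ins_prob[i], profile.rel_entropy[i]]) + "\n")
        w("END\n")
    finally:
        if close:
            stream.close()


def _expect(lines, prefix: str) -> str:
    try:
        line = next(lines)
    except StopIteration:
        raise ProfileFormatError(f"truncated profile: expected '{prefix}'")
    if not line.startswith(prefix):
        raise ProfileFormatError(
            f"malformed profile: expected '{prefix}', got '{line[:40]}'")
    return line[len(prefix):].strip()


def _read_profile_lines(lines) -> Profile:
    header = _expect(lines, _MAGIC)
    version = header.strip().lstrip("v")
    if version != FORMAT_VERSION:
        raise ProfileFormatError(
            f"profile format version mismatch: file v{version}, "
            f"reader v{FORMAT_VERSION}")
    name = _expect(lines, "name ")
    m = int(_expect(lines, "length "))
    table_name = _expect(lines, "table ")
    lambda_ref = float(_expect(lines, "lambda_ref "))
    source = _expect(lines, "source ")
    build_params = _expect(lines, "build_params ")

    f = np.empty((m, 20))
    gap = np.empty(m)
    t = np.empty((m, 20))
    s = np.empty((m, 20))
    extras = np.empty((m, 4))
    columns = np.empty(m, dtype=np.int64)
    for i in range(m):
        pos_line = _expect(lines, "pos ")
        columns[i] = int(pos_line.split("column")[1])
        f[i] = _floats(_expect(lines, "F "))
        gap[i] = float(_expect(lines, "G "))
        t[i] = _floats(_expect(lines, "T "))
        s[i] = _floats(_expect(lines, "S "))
        extras[i] = _floats(_expect(lines, "E "))
    _expect(lines, "END")
    # renormalize targets against printed-precision drift
    t /= t.sum(axis=1, keepdims=True)
    return Profile(
        name=name, obs_freq=f, gap_freq=gap, target=t, scores=s,
        eff_seqs=extras[:, 0], del_prob=extras[:, 1], ins_prob=extras[:, 2],
        rel_entropy=extras[:, 3], columns=columns, table_name=table_name,
        lambda_ref=lambda_ref, source=source, build_params=build_params)


def read_profile(stream) -> Profile:
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        with open(stream) as fh:
            return read_profile(fh)
    lines = (ln.rstrip("\n") for ln in stream if ln.strip())
    return _read_profile_lines(lines)


@dataclass
class ProfileDatabase:
    """A set of profiles with database-level reference statistics."""

    profiles: list[Profile]
    lambda_u: float = float("nan")
    K_u: float = float("nan")
    H_u: float = float("nan")
    n_vectors: int = 0
    provenance: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def total_positions(self) -> int:
        return sum(p.length for p in self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self):
        return len(self.profiles)


def write_database(db: ProfileDatabase, stream) -> None:
    close = False
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        stream = open(stream, "w")
        close = True
    try:
        w = stream.write
        w(f"{_DB_MAGIC} v{FORMAT_VERSION}\n")
        w(f"profiles {len(db.profiles)}\n")
        w(f"positions {db.total_positions}\n")
        w(f"vectors {db.n_vectors}\n")
        w(f"lambda_u {db.lambda_u:.10f}\n")
        w(f"K_u {db.K_u:.10f}\n")
        w(f"H_u {db.H_u:.10f}\n")
        w(f"provenance {db.provenance}\n")
        for prof in db.profiles:
            write_profile(prof, stream)
    finally:
        if close:
            stream.close()


def read_database(stream) -> ProfileDatabase:
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        with open(stream) as fh:
            return read_database(fh)
    lines = (ln.rstrip("\n") for ln in stream if ln.strip())
    _expect(lines, _DB_MAGIC)
    n_prof = int(_expect(lines, "profiles "))
    _expect(lines, "positions ")
    n_vectors = int(_expect(lines, "vectors "))
    lambda_u = float(_expect(lines, "lambda_u "))
    K_u = float(_expect(lines, "K_u "))
    H_u = float(_expect(lines, "H_u "))
    provenance = _expect(lines, "provenance ")
    profiles = [_read_profile_lines(lines) for _ in range(n_prof)]
    return ProfileDatabase(profiles=profiles, lambda_u=lambda_u, K_u=K_u,
                           H_u=H_u, n_vectors=n_vectors,
                           provenance=provenance)


def profile_to_string(profile: Profile) -> str:
    buf = io.StringIO()
    write_profile(profile, buf)
    return buf.getvalue()
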