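"""Control-file handling.

Simulation parameters live in a flat ``key = value`` text file with section
headers (``[pool]``, ``[map]``, ``[disease]``, ``[trait]``, ``[cohort]``,
``[output]``, ``[power]``) so parameter sets can be saved and reused.  Every
key is validated against a schema; unknown sections or keys are rejected
with their location.  Command-line flags override control-file values, which
override defaults.
"""

from __future__ import annotations

import configparser
from pathlib import Path

import numpy as np

from ._rng import substream
from .pool import HaplotypePool

__all__ = ["ControlFileError", "load_control", "merge_overrides",
           "parse_loci", "parse_float_list", "SCHEMA"]


class ControlFileError(ValueError):
    """A control file violated the schema; the message names the location."""


def _parse_bool(s: str) -> bool:
    v = s.strip().lower()
    if v in ("1", "true", "yes", "on"):
        return True
    if v in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


SCHEMA: dict[str, dict[str, type | object]] = {
    "pool": {
        "source": str,          # generate | matrix01 | vcf_phased | genome_out
        "n_haplotypes": int,
        "n_blocks": int,
        "theta": float,         # per-block scaled mutation rate
        "block_span": int,
        "chromosome": str,
        "haplotype_file": str,
        "sites_file": str,
    },
    "map": {
        "kind": str,            # fixed | hotspots
        "theta": float,         # per-interval recombination fraction (fixed)
        "hotspot_file": str,
    },
    "disease": {
        "model": str,           # prevalence | par
        "mode": str,
        "loci": str,            # "i,j,k" or "random:<n>:<maf_lo>:<maf_hi>[:block,...]"
        "K": float,
        "epsilon": float,
        "f0": float,
        "par_total": float,
        "par_scheme": str,
        "fixed_grr": float,
        "proportion_risk": float,
        "beta": str,            # scalar or comma list of log odds ratios
        "alpha": float,
        "risk_allele": str,
    },
    "trait": {
        "V_P": float,
        "f": str,               # scalar or comma list of variance fractions
        "V_poly": float,
        "mu": float,
        "mode": str,
        "qtl_loci": str,
        "ascertain": str,       # random | affected
    },
    "cohort": {
        "design": str,          # family | cc
        "n_families": int,
        "affected_sibs": int,
        "n_sibs": int,
        "n_cases": int,
        "n_controls": int,
        "fast_mode": _parse_bool,
        "pilot_cases": int,
        "workers": int,
        "seed": int,
    },
    "output": {
        "prefix": str,
    },
    "power": {
        "region": str,          # "block:<k>" or comma list of site indices
        "n_replicates": int,
        "alpha_level": float,
        "p_method": str,
    },
}


def load_control(path) -> dict[str, dict[str, object]]:
    """Parse and validate a control file into ``{section: {key: value}}``."""
    path = Path(path)
    if not path.exists():
        raise ControlFileError(f"control file not found: {path}")
    cp = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    cp.optionxform = str  # keys are case-sensitive (K, V_P, ...)
    try:
        cp.read(path)
    except configparser.Error as exc:
        raise ControlFileError(f"{path}: {exc}") from exc
    out: dict[str, dict[str, object]] = {}
    for section in cp.sections():
        if section not in SCHEMA:
            raise ControlFileError(
                f"{path}: unknown section [{section}] "
                f"(expected one of {sorted(SCHEMA)})"
            )
        out[section] = {}
        for key, raw in cp[section].items():
            if key not in SCHEMA[section]:
                raise ControlFileError(
                    f"{path}: unknown key {section}.{key} "
                    f"(allowed: {sorted(SCHEMA[section])})"
                )
            conv = SCHEMA[section][key]
            try:
                out[section][key] = conv(raw)  # type: ignore[operator]
            except ValueError as exc:
                raise ControlFileError(
                    f"{path}: bad value for {section}.{key}: {raw!r} ({exc})"
                ) from exc
    return out


def merge_overrides(
    cfg: dict[str, dict[str, object]],
    overrides: dict[tuple[str, str], object],
) -> dict[str, dict[str, object]]:
    """Apply (section, key) -> value overrides (CLI flags beat the file)."""
    out = {s: dict(kv) for s, kv in cfg.items()}
    for (section, key), value in overrides.items():
        if value is None:
            continue
        if section not in SCHEMA or key not in SCHEMA[section]:
            raise ControlFileError(f"unknown parameter {section}.{key}")
        out.setdefault(section, {})[key] = value
    return out


def parse_float_list(s: str | float, n: int, what: str) -> list[float]:
    """Parse a scalar (broadcast over n loci) or a comma list of length n."""
    if isinstance(s, (int, float)):
        return [float(s)] * n
    vals = [float(x) for x in str(s).split(",") if x.strip()]
    if len(vals) == 1:
        return vals * n
    if len(vals) != n:
        raise ControlFileError(
            f"{what}: expected 1 or {n} values, got {len(vals)}"
        )
    return vals


def parse_loci(spec: str, pool: HaplotypePool, seed: int, what: str) -> list[int]:
    """Parse a locus selector: either an explicit comma list of site indices
    or ``random:<n>:<maf_lo>:<maf_hi>[:<block,block,...>]`` for a seeded
    uniform draw among qualifying sites."""
    from .pool import select_causal_sites

    spec = str(spec).strip()
    if spec.startswith("random:"):
        parts = spec.split(":")
        if len(parts) not in (4, 5):
            raise ControlFileError(
                f"{what}: expected random:<n>:<maf_lo>:<maf_hi>[:<blocks>], "
                f"got {spec!r}"
            )
        n = int(parts[1])
        lo, hi = float(parts[2]), float(parts[3])
        blocks = None
        if len(parts) == 5:
            blocks = [int(b) for b in parts[4].split(",")]
        return select_causal_sites(pool, n, (lo, hi), blocks, seed)
    try:
        loci = [int(x) for x in spec.split(",") if x.strip()]
    except ValueError as exc:
        raise ControlFileError(f"{what}: bad locus list {spec!r}") from exc
    bad = [i for i in loci if not 0 <= i < pool.n_sites]
    if bad:
        raise ControlFileError(f"{what}: site indices out of range: {bad}")
    return loci


def parse_region(spec: str, pool: HaplotypePool, what: str) -> list[int]:
    """Parse a test-region selector: ``block:<k>``, ``all`` or a comma list
    of site indices."""
    spec = str(spec).strip()
    if spec == "all":
        return list(range(pool.n_sites))
    if spec.startswith("block:"):
        blocks = [int(b) for b in spec.split(":", 1)[1].split(",")]
        idx = np.flatnonzero(np.isin(pool.block_ids, blocks))
        if len(idx) == 0:
            raise ControlFileError(f"{what}: no sites in blocks {blocks}")
        return [int(i) for i in idx]
    return parse_loci(spec, pool, 0, what)
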