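"""Configuration and matrix I/O.

Experiment configuration files are YAML with a strict schema: unknown
keys are rejected by name, defaults are filled from the dataclass
defaults of the target module, and the fully-resolved configuration can
be dumped next to the outputs of a run.

Snapshot matrices travel either as delimited text (genes x cells with a
header row of cell ids and a first column of gene ids) or as MatrixMarket
sparse files with ``.genes.txt`` / ``.cells.txt`` sidecar identifier
lists.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .abm import ABMConfig, Genotype, TherapySchedule
from .crn import CRNRates
from .grn import GRNParams, SnapshotMatrix
from .landscape import LandscapeSpec, double_well

__all__ = [
    "ExperimentConfig", "load_config", "preset_path", "list_presets",
    "read_matrix", "write_matrix",
]

MODULES = ("abm", "crn", "grn", "landscape", "index")


class ConfigError(ValueError):
    """A configuration file violated the schema."""


def _check_keys(block: dict, allowed: set[str], context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context} "
            f"(allowed: {sorted(allowed)})")


def _field_names(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def _build_rates(block: dict) -> CRNRates:
    _check_keys(block, _field_names(CRNRates), "crn_rates block")
    return CRNRates(**block)


def _build_genotype(block: dict) -> Genotype:
    _check_keys(block, {"g_s", "g_r"}, "genotype block")
    try:
        return Genotype(**block)
    except TypeError as err:
        raise ConfigError(f"genotype block: {err}") from err


def _build_abm(block: dict) -> ABMConfig:
    allowed = _field_names(ABMConfig)
    _check_keys(block, allowed, "abm block")
    kwargs = dict(block)
    if "genotype" in kwargs:
        kwargs["genotype"] = _build_genotype(dict(kwargs["genotype"]))
    if "crn_rates" in kwargs:
        kwargs["crn_rates"] = _build_rates(dict(kwargs["crn_rates"]))
    try:
        return ABMConfig(**kwargs)
    except ValueError as err:
        raise ConfigError(f"abm block: {err}") from err


def _build_therapy(block: dict) -> TherapySchedule:
    _check_keys(block, _field_names(TherapySchedule), "therapy block")
    try:
        return TherapySchedule(**block)
    except ValueError as err:
        raise ConfigError(f"therapy block: {err}") from err


def _build_grn(block: dict) -> GRNParams:
    _check_keys(block, _field_names(GRNParams), "grn block")
    try:
        return GRNParams(**block)
    except ValueError as err:
        raise ConfigError(f"grn block: {err}") from err


_LANDSCAPE_KEYS = {"barrier", "diffusion", "growth", "x_min", "x_max", "n_grid"}


def _build_landscape(block: dict) -> LandscapeSpec:
    _check_keys(block, _LANDSCAPE_KEYS, "landscape block")
    kwargs = dict(block)
    barrier = kwargs.pop("barrier", 1.0)
    try:
        return LandscapeSpec(potential=double_well(barrier), **kwargs)
    except ValueError as err:
        raise ConfigError(f"landscape block: {err}") from err


@dataclass
class ExperimentConfig:
    """Validated, fully-resolved experiment description."""

    module: str
    seed: int = 0
    abm: ABMConfig | None = None
    therapy: TherapySchedule | None = None
    grn: GRNParams | None = None
    landscape: LandscapeSpec | None = None
    crn: dict | None = None
    index: dict | None = None
    source: str | None = None

    def resolved_dict(self) -> dict:
        """Fully-resolved configuration (defaults included) as plain data."""
        out: dict = {"module": self.module, "seed": self.seed}
        if self.abm is not None:
            out["abm"] = dataclasses.asdict(self.abm)
        if self.therapy is not None:
            out["therapy"] = dataclasses.asdict(self.therapy)
        if self.grn is not None:
            out["grn"] = dataclasses.asdict(self.grn)
        if self.landscape is not None:
            spec = self.landscape
            out["landscape"] = {
                "barrier": float(spec.V(np.array([0.0]))[0]),
                "diffusion": spec.diffusion if not callable(spec.diffusion) else "callable",
                "growth": spec.growth if not callable(spec.growth) else "callable",
                "x_min": spec.x_min, "x_max": spec.x_max, "n_grid": spec.n_grid,
            }
        if self.crn is not None:
            out["crn"] = dict(self.crn)
        if self.index is not None:
            out["index"] = dict(self.index)
        return out

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.resolved_dict(),
                                             sort_keys=False))


_TOP_KEYS = {"module", "seed", "abm", "therapy", "grn", "landscape", "crn", "index"}
_CRN_KEYS = {"total", "fractions", "fraction_step", "n_reps", "rates"}
_INDEX_KEYS = {"pair_subsample"}


def preset_path(name: str) -> Path:
    """Path of a shipped preset configuration (e.g. ``fig11c``)."""
    base = resources.files("plastisim") / "presets" / f"{name}.yaml"
    with resources.as_file(base) as p:
        if not p.exists():
            raise FileNotFoundError(
                f"no shipped preset {name!r}; available: {list_presets()}")
        return Path(p)


def list_presets() -> list[str]:
    folder = resources.files("plastisim") / "presets"
    return sorted(p.name[:-5] for p in folder.iterdir() if p.name.endswith(".yaml"))


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment configuration.

    ``path`` may be a file path or the bare name of a shipped preset.
    Raises :class:`ConfigError` naming the offending key on any schema
    violation, and ``FileNotFoundError`` for a missing file.
    """
    p = Path(path)
    if not p.exists() and p.suffix == "" and "/" not in str(path):
        p = preset_path(str(path))
    if not p.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    raw = yaml.safe_load(p.read_text())
    if raw is None:
        raise ConfigError(
            "empty configuration: a 'module' key is required, plus the "
            f"matching parameter block from {sorted(_TOP_KEYS - {'module', 'seed'})}")
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    module = raw.get("module")
    if module not in MODULES:
        raise ConfigError(f"'module' must be one of {MODULES}, got {module!r}")
    cfg = ExperimentConfig(module=module, seed=int(raw.get("seed", 0)),
                           source=str(p))
    if "abm" in raw:
        cfg.abm = _build_abm(dict(raw["abm"]))
    if "therapy" in raw:
        cfg.therapy = _build_therapy(dict(raw["therapy"]))
    if "grn" in raw:
        cfg.grn = _build_grn(dict(raw["grn"]))
    if "landscape" in raw:
        cfg.landscape = _build_landscape(dict(raw["landscape"]))
    if "crn" in raw:
        block = dict(raw["crn"])
        _check_keys(block, _CRN_KEYS, "crn block")
        if "rates" in block:
            block["rates"] = _build_rates(dict(block["rates"]))
        cfg.crn = block
    if "index" in raw:
        block = dict(raw["index"])
        _check_keys(block, _INDEX_KEYS, "index block")
        cfg.index = block
    if module == "abm" and cfg.abm is None:
        cfg.abm = ABMConfig()
    if module == "abm" and cfg.therapy is None:
        cfg.therapy = TherapySchedule()
    if module == "grn" and cfg.grn is None:
        cfg.grn = GRNParams()
    if module == "landscape" and cfg.landscape is None:
        cfg.landscape = LandscapeSpec()
    if module == "crn" and cfg.crn is None:
        cfg.crn = {}
    return cfg


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(path, matrix: SnapshotMatrix, fmt: str | None = None) -> None:
    """Write a snapshot matrix as delimited text or MatrixMarket.

    Format is inferred from the suffix (``.mtx`` vs anything else) unless
    given. MTX output adds ``.genes.txt`` and ``.cells.txt`` sidecars.
    """
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt == "tsv":
        frame = pd.DataFrame(matrix.values, index=matrix.genes,
                             columns=matrix.cells)
        frame.to_csv(path, sep="\t", index_label="gene")
    elif fmt == "mtx":
        scipy.io.mmwrite(str(path), sp.csr_matrix(matrix.values))
        path.with_suffix(".genes.txt").write_text("\n".join(matrix.genes) + "\n")
        path.with_suffix(".cells.txt").write_text("\n".join(matrix.cells) + "\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r} (use 'tsv' or 'mtx')")


def read_matrix(path, fmt: str | None = None,
                condition: str = "") -> SnapshotMatrix:
    """Read a snapshot matrix written by :func:`write_matrix`.

    Raises ``ValueError`` (with the offending file named) on malformed
    input; no partial result is returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    fmt = fmt or ("mtx" if path.suffix == ".mtx" else "tsv")
    if fmt not in ("tsv", "mtx"):
        raise ValueError(f"unknown matrix format {fmt!r}")
    try:
        if fmt == "tsv":
            frame = pd.read_csv(path, sep="\t", index_col=0)
            if frame.empty or frame.isna().any().any():
                raise ValueError("missing values or empty table")
            values = frame.to_numpy(dtype=float)
            genes = [str(g) for g in frame.index]
            cells = [str(c) for c in frame.columns]
        elif fmt == "mtx":
            values = np.asarray(scipy.io.mmread(str(path)).todense(), dtype=float)
            genes = path.with_suffix(".genes.txt").read_text().split()
            cells = path.with_suffix(".cells.txt").read_text().split()
    except Exception as err:
        raise ValueError(f"failed to parse {path}: {err}") from err
    try:
        return SnapshotMatrix(values=values, genes=genes, cells=cells,
                              condition=condition)
    except ValueError as err:
        raise ValueError(f"malformed matrix in {path}: {err}") from err
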