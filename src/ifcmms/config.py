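"""Flat key/value config files mirroring the CLI flags.

The file is YAML restricted to a flat mapping; nested options use dotted
keys (``transfer.radius: 2``). Unknown keys are rejected so typos surface
immediately.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .clustering import AlgoConfig, SimilarityOptions
from .fuzzy_sets import GeneratorParams
from .transfer import GuidedFilterParams

_TOP_KEYS = {
    "clusters": ("c", int),
    "m": ("m", float),
    "eta": ("eta", float),
    "max_iter": ("max_iter", int),
    "seed": ("seed", int),
    "use_ifs": ("use_ifs", bool),
    "use_transfer": ("use_transfer", bool),
    "use_similarity": ("use_similarity", bool),
    "center_weights_powered": ("center_weights_powered", bool),
    "fixed_gray_scale": ("fixed_gray_scale", float),
}

_GEN_KEYS = {"generator.family": ("family", str), "generator.param": ("param", float)}
_TRANSFER_KEYS = {
    "transfer.radius": ("radius", int),
    "transfer.eps": ("eps", float),
    "transfer.subsample": ("subsample", int),
    "transfer.median_radius": ("median_radius", int),
}
_SIM_KEYS = {
    "similarity.mode": ("mode", str),
    "similarity.window_radius": ("window_radius", int),
    "similarity.scale_floor": ("scale_floor", float),
}


def load_config(path: str | Path, base: AlgoConfig | None = None) -> AlgoConfig:
    """Read a flat config file into an :class:`AlgoConfig`.

    ``transfer.enabled`` is an alias for ``use_transfer``.
    """
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key/value mapping")
    cfg = base or AlgoConfig()
    top: dict = {}
    gen: dict = {}
    tra: dict = {}
    sim: dict = {}
    for key, value in data.items():
        if key == "transfer.enabled":
            top["use_transfer"] = bool(value)
        elif key in _TOP_KEYS:
            name, cast = _TOP_KEYS[key]
            top[name] = None if value is None else cast(value)
        elif key in _GEN_KEYS:
            name, cast = _GEN_KEYS[key]
            gen[name] = cast(value)
        elif key in _TRANSFER_KEYS:
            name, cast = _TRANSFER_KEYS[key]
            tra[name] = cast(value)
        elif key in _SIM_KEYS:
            name, cast = _SIM_KEYS[key]
            sim[name] = cast(value)
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")
    if gen:
        top["generator"] = replace(cfg.generator, **gen)
    if tra:
        top["transfer"] = replace(cfg.transfer, **tra)
    if sim:
        top["similarity"] = replace(cfg.similarity, **sim)
    return replace(cfg, **top)


def config_dict(cfg: AlgoConfig) -> dict:
    """Flat dict form of a config (the inverse of :func:`load_config`)."""
    return {
        "clusters": cfg.c,
        "m": cfg.m,
        "eta": cfg.eta,
        "max_iter": cfg.max_iter,
        "seed": cfg.seed,
        "use_ifs": cfg.use_ifs,
        "use_transfer": cfg.use_transfer,
        "use_similarity": cfg.use_similarity,
        "center_weights_powered": cfg.center_weights_powered,
        "fixed_gray_scale": cfg.fixed_gray_scale,
        "generator.family": cfg.generator.family,
        "generator.param": cfg.generator.param,
        "transfer.radius": cfg.transfer.radius,
        "transfer.eps": cfg.transfer.eps,
        "transfer.subsample": cfg.transfer.subsample,
        "transfer.median_radius": cfg.transfer.median_radius,
        "similarity.mode": cfg.similarity.mode,
        "similarity.window_radius": cfg.similarity.window_radius,
        "similarity.scale_floor": cfg.similarity.scale_floor,
    }
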