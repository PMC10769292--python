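"""File I/O: images, 3-class label masks, graphs, configurations.

Images are 2D grayscale TIFF or PNG (8/16-bit).  Label masks are written as
single-channel indexed PNGs with values {0, 1, 2}.  Graphs round-trip through
GraphML (scalar node/edge attributes preserved; planted centreline paths are
not serialised).  Configurations are flat key-value TOML.
"""

from __future__ import annotations

import ast
import dataclasses
import tomllib
from pathlib import Path

import imageio.v3 as iio
import networkx as nx
import numpy as np
import tifffile

from .graph import LcnGraph
from .synthetic import SceneConfig
from .threshold import ThresholdConfig

__all__ = [
    "read_image",
    "write_image",
    "read_label",
    "write_label",
    "read_graph",
    "write_graph",
    "read_config",
    "write_config",
]


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3:  # RGB(A): confocal signal lives in the red channel
        img = img[..., 0]
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2D grayscale image, got shape {img.shape}")
    return img


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def read_label(path: str | Path) -> np.ndarray:
    label = np.asarray(iio.imread(Path(path)))
    if label.ndim == 3:
        label = label[..., 0]
    if not set(np.unique(label)) <= {0, 1, 2}:
        raise ValueError(f"{path}: not a 3-class label mask")
    return label.astype(np.uint8)


def write_label(path: str | Path, label: np.ndarray) -> None:
    label = np.asarray(label).astype(np.uint8)
    if not set(np.unique(label)) <= {0, 1, 2}:
        raise ValueError("label mask must contain only classes {0, 1, 2}")
    iio.imwrite(Path(path), label)


def write_graph(path: str | Path, graph: LcnGraph) -> None:
    g = graph.to_networkx()
    # GraphML has no list type: encode graph-level records as literals
    g.graph["dead_ends"] = repr(g.graph["dead_ends"])
    g.graph["isolated_dendrites"] = repr(g.graph["isolated_dendrites"])
    nx.write_graphml(g, str(path))


def read_graph(path: str | Path) -> LcnGraph:
    g = nx.read_graphml(str(path), node_type=int, force_multigraph=True)
    g.graph["dead_ends"] = ast.literal_eval(g.graph.get("dead_ends", "[]"))
    g.graph["isolated_dendrites"] = ast.literal_eval(g.graph.get("isolated_dendrites", "[]"))
    return LcnGraph.from_networkx(g)


_CONFIG_TYPES = {"scene": SceneConfig, "threshold": ThresholdConfig}


def write_config(path: str | Path, config) -> None:
    """Write a dataclass config as flat TOML under a section named by its kind."""
    for section, cls in _CONFIG_TYPES.items():
        if isinstance(config, cls):
            break
    else:
        raise TypeError(f"unsupported config type {type(config).__name__}")
    lines = [f"[{section}]"]
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = list(value)
        lines.append(f"{f.name} = {_toml_value(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return f'"{value}"'
    if isinstance(value, list):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    if value is None:
        raise TypeError("TOML has no null; drop the key instead")
    raise TypeError(f"unsupported TOML value {value!r}")


def read_config(path: str | Path):
    """Read a flat TOML config; the single section names the config kind."""
    data = tomllib.loads(Path(path).read_text())
    if len(data) != 1:
        raise ValueError(f"{path}: expected exactly one config section")
    section, values = next(iter(data.items()))
    try:
        cls = _CONFIG_TYPES[section]
    except KeyError:
        raise ValueError(f"{path}: unknown config section [{section}]") from None
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in values.items():
        if key not in fields:
            raise ValueError(f"{path}: unknown key {key!r} in [{section}]")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)
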