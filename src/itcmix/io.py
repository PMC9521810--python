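"""Reading and writing heat files and posterior-sample tables.

Heat files are delimiter-separated text with two mandatory columns,
``injection_volume_uL`` and ``heat_ucal`` (instrument-convention units),
and optional ``#``-prefixed metadata lines::

    # cell_volume_mL=1.3513
    # temperature_K=300
    # stated_R0_mM=0.05
    # stated_Ls_mM=1.0
    injection_volume_uL,heat_ucal
    12.0,-31.2
    ...

Internally volumes are litres, heats cal and concentrations mol/L.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .models import DEFAULT_CELL_VOLUME, DEFAULT_TEMPERATURE, TitrationProtocol
from .probability import Dataset
from .sampling import PosteriorSamples, SamplerConfig

__all__ = ["read_heat_file", "write_heat_file", "save_samples", "load_samples"]

_META_KEYS = {"cell_volume_mL", "temperature_K", "stated_R0_mM", "stated_Ls_mM"}


class HeatFileError(ValueError):
    """Raised on a malformed heat file, naming the offending line."""


def read_heat_file(path: str | Path) -> Dataset:
    """Parse a heat file into a :class:`Dataset`."""
    path = Path(path)
    meta: dict[str, float] = {}
    rows: list[tuple[float, float]] = []
    header_seen = False
    col_idx = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key in _META_KEYS:
                        try:
                            meta[key] = float(val)
                        except ValueError:
                            raise HeatFileError(
                                f"{path}:{lineno}: bad metadata value {val!r}"
                            ) from None
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",") if p.strip()]
            if not header_seen:
                try:
                    col_idx = {
                        "vol": parts.index("injection_volume_uL"),
                        "heat": parts.index("heat_ucal"),
                    }
                except ValueError:
                    raise HeatFileError(
                        f"{path}:{lineno}: header must name columns "
                        "injection_volume_uL and heat_ucal"
                    ) from None
                header_seen = True
                continue
            try:
                rows.append(
                    (float(parts[col_idx["vol"]]), float(parts[col_idx["heat"]]))
                )
            except (ValueError, IndexError):
                raise HeatFileError(f"{path}:{lineno}: malformed data row") from None
    if not rows:
        raise HeatFileError(f"{path}: no data rows found")
    vols_uL, heats_ucal = map(np.array, zip(*rows))
    protocol = TitrationProtocol(
        injection_volumes=vols_uL * 1e-6,
        cell_volume=meta.get("cell_volume_mL", DEFAULT_CELL_VOLUME * 1e3) * 1e-3,
        temperature=meta.get("temperature_K", DEFAULT_TEMPERATURE),
    )
    r0 = meta.get("stated_R0_mM")
    ls = meta.get("stated_Ls_mM")
    return Dataset(
        heats=heats_ucal * 1e-6,
        protocol=protocol,
        stated_R0=r0 * 1e-3 if r0 is not None else None,
        stated_Ls=ls * 1e-3 if ls is not None else None,
    )


def write_heat_file(path: str | Path, data: Dataset) -> None:
    """Write a :class:`Dataset` in the heat-file format (µL / µcal / mM)."""
    path = Path(path)
    lines = [
        f"# cell_volume_mL={data.protocol.cell_volume * 1e3:.6g}",
        f"# temperature_K={data.protocol.temperature:.6g}",
    ]
    if data.stated_R0 is not None:
        lines.append(f"# stated_R0_mM={data.stated_R0 * 1e3:.6g}")
    if data.stated_Ls is not None:
        lines.append(f"# stated_Ls_mM={data.stated_Ls * 1e3:.6g}")
    lines.append("injection_volume_uL,heat_ucal")
    for dv, q in zip(data.protocol.injection_volumes, data.heats):
        lines.append(f"{dv * 1e6:.6g},{q * 1e6:.10g}")
    path.write_text("\n".join(lines) + "\n")


def save_samples(path: str | Path, samples: PosteriorSamples) -> None:
    """Persist retained draws as CSV plus a JSON config sidecar."""
    path = Path(path)
    df = samples.to_frame()
    df["log_post"] = samples.log_post
    header = ",".join(
        f"{n}[{u}]" if u else n for n, u in zip(samples.names, samples.units)
    )
    with open(path, "w") as fh:
        fh.write(f"# model={samples.model}\n# columns={header},log_post\n")
        df.to_csv(fh, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = asdict(samples.config)
    if not isinstance(cfg.get("init"), str):
        cfg["init"] = "supplied"
    sidecar.write_text(
        json.dumps({"model": samples.model, "config": cfg}, indent=1)
    )


def load_samples(path: str | Path) -> PosteriorSamples:
    """Load a sample table written by :func:`save_samples`."""
    path = Path(path)
    model = "EM"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# model="):
            model = first.split("=", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    lp = df.pop("log_post").to_numpy()
    sidecar = path.with_suffix(path.suffix + ".json")
    config = SamplerConfig()
    if sidecar.exists():
        raw = json.loads(sidecar.read_text()).get("config", {})
        raw = {k: v for k, v in raw.items() if k in SamplerConfig.__dataclass_fields__}
        config = SamplerConfig(**raw)
    return PosteriorSamples(
        values=df.to_numpy(dtype=float),
        names=tuple(df.columns),
        model=model,
        config=config,
        log_post=lp,
    )
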