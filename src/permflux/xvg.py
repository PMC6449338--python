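"""Reading and writing umbrella-window time series in pull-code XVG dialect.

Each window is stored as a pair of two-column text files — ``pullx``
(time/position) and ``pullf`` (time/force) — with ``#`` and ``@`` comment
headers, plus a single ``manifest.json`` recording the restraint
parameters, sampling interval and seed for the whole set.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .membrane1d import UmbrellaWindow, WindowSet

MANIFEST_NAME = "manifest.json"


def write_xvg(path, x, y, title: str = "", xaxis: str = "Time (ps)",
              yaxis: str = "") -> None:
    """Write a two-column whitespace-separated series with @/# headers."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# written by permflux\n")
        fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis  label "{xaxis}"\n')
        fh.write(f'@    yaxis  label "{yaxis}"\n')
        fh.write("@TYPE xy\n")
        for xi, yi in zip(np.asarray(x), np.asarray(y)):
            fh.write(f"{xi:.6f}\t{yi:.8g}\n")


def read_xvg(path) -> tuple:
    """Read a two-column XVG file, skipping #/@ comment lines."""
    xs, ys = [], []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "@")):
                continue
            parts = line.split()
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
    return np.asarray(xs), np.asarray(ys)


def write_window_set(window_set: WindowSet, directory, seed: int | None = None) -> Path:
    """Write pullx/pullf XVG pairs plus a JSON manifest; returns the dir."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, w in enumerate(window_set.windows):
        stem = f"{w.replicate_id}_win{i:03d}"
        t = np.arange(w.n_samples) * w.timestep_between_samples
        write_xvg(directory / f"pullx_{stem}.xvg", t, w.positions,
                  title="Pull COM", yaxis="Position (nm)")
        write_xvg(directory / f"pullf_{stem}.xvg", t, w.forces,
                  title="Pull force", yaxis="Force (kJ/mol/nm)")
        entries.append(
            {
                "pullx": f"pullx_{stem}.xvg",
                "pullf": f"pullf_{stem}.xvg",
                "center": w.center,
                "spring_constant": w.spring_constant,
                "replicate_id": w.replicate_id,
                "timestep_between_samples": w.timestep_between_samples,
            }
        )
    manifest = {"spacing": window_set.spacing, "seed": seed, "windows": entries}
    (directory / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return directory


def read_window_set(directory) -> WindowSet:
    """Reconstruct a WindowSet from a manifest directory.

    If a window's ``pullf`` file is missing, the restraint force
    -k_u (z - z0) is reconstructed from the positions (the landscape
    contribution is then absent; downstream force-correlation estimates
    carry that caveat).
    """
    directory = Path(directory)
    manifest = json.loads((directory / MANIFEST_NAME).read_text())
    windows = []
    for e in manifest["windows"]:
        _, pos = read_xvg(directory / e["pullx"])
        pullf = directory / e["pullf"]
        if pullf.exists():
            _, frc = read_xvg(pullf)
        else:
            frc = -e["spring_constant"] * (pos - e["center"])
        windows.append(
            UmbrellaWindow(
                center=e["center"],
                spring_constant=e["spring_constant"],
                positions=pos,
                forces=frc,
                timestep_between_samples=e["timestep_between_samples"],
                replicate_id=e["replicate_id"],
            )
        )
    return WindowSet(windows=tuple(windows), spacing=manifest["spacing"])
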