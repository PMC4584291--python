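"""Plain-text table formats: form factors, density profiles, scan results.

All formats are TSV with a header row; comment lines starting with ``#``
carry scale/weighting annotations so tables round-trip losslessly.
"""

from __future__ import annotations

import json

import numpy as np

from .density import DensityProfile
from .fitting import ScanTable
from .formfactor import FormFactor


def _fmt(v: float) -> str:
    return repr(float(v))  # shortest exact round-trip representation


def write_formfactor_table(path, ff: FormFactor) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale_status: {ff.scale_status}\n")
        if ff.delta is None:
            fh.write("qz\tF\n")
            for q, a in zip(ff.qz, ff.amplitude):
                fh.write(f"{_fmt(q)}\t{_fmt(a)}\n")
        else:
            fh.write("qz\tF\tdelta\n")
            for q, a, d in zip(ff.qz, ff.amplitude, ff.delta):
                fh.write(f"{_fmt(q)}\t{_fmt(a)}\t{_fmt(d)}\n")


def read_formfactor_table(path) -> FormFactor:
    scale_status = "arbitrary"
    qz, amp, delta = [], [], []
    has_delta = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "scale_status:" in line:
                    scale_status = line.split("scale_status:")[1].strip()
                continue
            fields = line.split("\t")
            if fields[0] == "qz":  # header row
                has_delta = len(fields) >= 3
                continue
            try:
                vals = [float(x) for x in fields]
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: unparseable row: {line!r}") from err
            if has_delta and len(vals) >= 3:
                delta.append(vals[2])
            qz.append(vals[0])
            amp.append(vals[1])
            if len(qz) >= 2 and qz[-1] <= qz[-2]:
                raise ValueError(f"{path}:{lineno}: qz not strictly ascending")
            if vals[1] < 0:
                raise ValueError(f"{path}:{lineno}: negative amplitude {vals[1]!r}")
    if not qz:
        raise ValueError(f"{path}: no data rows")
    return FormFactor(
        np.asarray(qz),
        np.asarray(amp),
        delta=np.asarray(delta) if delta else None,
        scale_status=scale_status,
    )


def write_profile_table(path, profiles: dict[str, DensityProfile]) -> None:
    """One z column plus one column per component; weighting in the header."""
    labels = [lbl for lbl in profiles if lbl != "total"] + (
        ["total"] if "total" in profiles else []
    )
    first = profiles[labels[0]]
    weighting = first.weighting
    z = first.bin_centers
    for lbl in labels:
        if not np.allclose(profiles[lbl].bin_centers, z):
            raise ValueError("all profiles must share one bin grid")
    with open(path, "w") as fh:
        fh.write(f"# weighting: {weighting}\n")
        fh.write(f"# n_frames: {first.n_frames}\n")
        fh.write("z\t" + "\t".join(labels) + "\n")
        for i in range(z.size):
            row = [_fmt(z[i])] + [_fmt(profiles[lbl].values[i]) for lbl in labels]
            fh.write("\t".join(row) + "\n")


def read_profile_table(path) -> dict[str, DensityProfile]:
    weighting = "electron"
    n_frames = 1
    labels: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "weighting:" in line:
                    weighting = line.split("weighting:")[1].strip()
                if "n_frames:" in line:
                    n_frames = int(line.split("n_frames:")[1].strip())
                continue
            fields = line.split("\t")
            if fields[0] == "z":
                labels = fields[1:]
                continue
            try:
                rows.append([float(x) for x in fields])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: unparseable row: {line!r}") from err
    if labels is None or not rows:
        raise ValueError(f"{path}: missing header or data")
    data = np.asarray(rows)
    z = data[:, 0]
    return {
        lbl: DensityProfile(z, data[:, j + 1], weighting=weighting, component=lbl,
                            n_frames=n_frames)
        for j, lbl in enumerate(labels)
    }


def write_scan_table(path, table: ScanTable) -> None:
    df = table.to_dataframe().sort_values(["z", "A_L", "replicate"])
    with open(path, "w") as fh:
        fh.write("z\tA_L\treplicate\tchi2\ta_sim\taccepted\n")
        for _, r in df.iterrows():
            fh.write(
                f"{r['z']:.12g}\t{r['A_L']:.12g}\t{int(r['replicate'])}\t"
                f"{r['chi2']:.12g}\t{r['a_sim']:.12g}\t{str(bool(r['accepted'])).lower()}\n"
            )


def write_scan_summary(path, table: ScanTable) -> None:
    with open(path, "w") as fh:
        json.dump(table.summary(), fh, indent=2)
        fh.write("\n")
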