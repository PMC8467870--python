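"""Minimal WFDB-compatible record I/O (format 16).

Implements the subset of the PhysioNet waveform-database dialect the
pipeline touches: a text ``.hea`` header naming the signals plus a single
interleaved little-endian 16-bit ``.dat`` file, with per-signal
gain/baseline conversion to physical units.  This is enough both to read
challenge-style polysomnography records and to let the synthetic generator
write records that exercise the same reader.

Arousal annotations travel as a sidecar per-sample 0/1 vector, stored
either as ``<record>.labels.npy`` or as a plain text file of 0/1 lines
(``<record>.labels.txt``); absent annotations read back as all-zero labels
with a warning.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

from .synthetic import EEGRecord

__all__ = ["write_wfdb", "read_wfdb_record", "read_wfdb_signals"]

_ADC_TARGET = 32000  # peak ADC amplitude the writer scales to


def write_wfdb(
    path_stem: str | Path,
    signals: np.ndarray,
    sampling_rate: float,
    channel_names: list[str],
    labels: np.ndarray | None = None,
    label_format: str = "npy",
) -> None:
    """Write a multi-channel record as ``stem.hea`` + ``stem.dat``.

    ``signals`` is (n_samples,) or (n_samples, n_channels), in physical
    units; each channel is scaled to 16-bit integers with its own gain
    (recorded in the header) so the round trip is accurate to the 16-bit
    quantization step.
    """
    path_stem = Path(path_stem)
    x = np.asarray(signals, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n_samples, n_sig = x.shape
    if len(channel_names) != n_sig:
        raise ValueError("one channel name per signal required")

    gains = np.empty(n_sig)
    adc = np.empty((n_samples, n_sig), dtype="<i2")
    for j in range(n_sig):
        peak = np.abs(x[:, j]).max()
        gains[j] = _ADC_TARGET / peak if peak > 0 else 1.0
        adc[:, j] = np.clip(np.round(x[:, j] * gains[j]), -32768, 32767).astype("<i2")

    dat_name = path_stem.with_suffix(".dat").name
    lines = [f"{path_stem.stem} {n_sig} {sampling_rate:g} {n_samples}"]
    for j, name in enumerate(channel_names):
        first = int(adc[0, j])
        checksum = int(adc[:, j].astype(np.int64).sum() % 65536)
        lines.append(
            f"{dat_name} 16 {gains[j]:.6f}(0)/au 16 0 {first} {checksum} 0 {name}"
        )
    path_stem.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    adc.tofile(path_stem.with_suffix(".dat"))

    if labels is not None:
        lab = np.asarray(labels, dtype=np.int8)
        if len(lab) != n_samples:
            raise ValueError("labels must match the record length")
        if label_format == "npy":
            np.save(path_stem.parent / (path_stem.stem + ".labels.npy"), lab)
        elif label_format == "txt":
            np.savetxt(path_stem.parent / (path_stem.stem + ".labels.txt"), lab, fmt="%d")
        else:
            raise ValueError("label_format must be 'npy' or 'txt'")


_SIGNAL_RE = re.compile(
    r"^(?P<file>\S+)\s+(?P<fmt>\d+)\s+(?P<gain>[-\d.eE+]+)"
    r"(?:\((?P<baseline>[-\d]+)\))?(?:/(?P<units>\S+))?"
    r"(?:\s+(?P<rest>.*))?$"
)


def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"corrupt header {hea_path}: {lines[0]!r}")
    record_name, n_sig = head[0], int(head[1])
    fs, n_samples = float(head[2]), int(head[3])
    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) != n_sig:
        raise ValueError(f"corrupt header {hea_path}: expected {n_sig} signal lines")
    signals = []
    for ln in sig_lines:
        m = _SIGNAL_RE.match(ln)
        if not m:
            raise ValueError(f"corrupt signal line in {hea_path}: {ln!r}")
        if m.group("fmt") != "16":
            raise ValueError(f"unsupported WFDB format {m.group('fmt')} (only 16)")
        rest = (m.group("rest") or "").split()
        # trailing fields: adc_res adc_zero init_value checksum block_size description...
        description = " ".join(rest[5:]) if len(rest) > 5 else f"ch{len(signals)}"
        signals.append(
            {
                "file": m.group("file"),
                "gain": float(m.group("gain")),
                "baseline": int(m.group("baseline") or 0),
                "name": description,
            }
        )
    return record_name, fs, n_samples, signals


def read_wfdb_signals(path_stem: str | Path):
    """Read all channels: (data (n_samples, n_sig) physical, names, fs)."""
    path_stem = Path(path_stem)
    record_name, fs, n_samples, signals = _parse_header(path_stem.with_suffix(".hea"))
    dat_path = path_stem.parent / signals[0]["file"]
    raw = np.fromfile(dat_path, dtype="<i2")
    n_sig = len(signals)
    if raw.size != n_samples * n_sig:
        raise ValueError(
            f"{dat_path} holds {raw.size} samples, header promises {n_samples * n_sig}"
        )
    adc = raw.reshape(n_samples, n_sig)
    data = np.empty((n_samples, n_sig), dtype=np.float64)
    names = []
    for j, sig in enumerate(signals):
        gain = sig["gain"] if sig["gain"] != 0 else 1.0
        data[:, j] = (adc[:, j].astype(np.float64) - sig["baseline"]) / gain
        names.append(sig["name"])
    return data, names, fs


def _load_labels(path_stem: Path, n_samples: int) -> np.ndarray | None:
    npy = path_stem.parent / (path_stem.stem + ".labels.npy")
    txt = path_stem.parent / (path_stem.stem + ".labels.txt")
    if npy.exists():
        lab = np.load(npy)
    elif txt.exists():
        lab = np.loadtxt(txt, dtype=np.int8)
    else:
        return None
    lab = np.asarray(lab, dtype=np.int8).ravel()
    if len(lab) != n_samples:
        raise ValueError(
            f"label vector length {len(lab)} does not match record length {n_samples}"
        )
    return lab


def read_wfdb_record(path_stem: str | Path, channel: str = "C3-M2") -> EEGRecord:
    """Read one channel of a WFDB record as an :class:`EEGRecord`.

    Raises a ``KeyError`` naming the available channels when the requested
    one is missing; a missing annotation sidecar yields all-zero labels with
    a warning.
    """
    path_stem = Path(path_stem)
    data, names, fs = read_wfdb_signals(path_stem)
    if channel not in names:
        raise KeyError(
            f"channel {channel!r} not in record; available channels: {names}"
        )
    x = data[:, names.index(channel)]
    labels = _load_labels(path_stem, len(x))
    if labels is None:
        warnings.warn(
            f"no arousal annotations found for {path_stem.stem}; labels set to all zero",
            stacklevel=2,
        )
        labels = np.zeros(len(x), dtype=np.int8)
    return EEGRecord(samples=x, labels=labels, sampling_rate=fs,
                     record_id=path_stem.stem)
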