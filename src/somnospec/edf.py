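"""EDF container I/O.

Recordings are stored as plain EDF (one file per animal; 16-bit samples,
1-s data records) plus a JSON sidecar ``<file>.json`` carrying the channel
role map and lights-on window, since EDF labels alone are too constrained.

Writing is implemented directly against the EDF header layout; reading
goes through mne's EDF reader, which also serves as an independent check
on the writer in the test suite. Signals are quantized to the 16-bit
digital range per channel, so a round-trip is exact only up to that
quantization step.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import numpy as np

from .recording import Recording

_DIG_MAX = 32767
_DIG_MIN = -32767


def _pad(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {value!r} > {width} bytes")
    return b.ljust(width)


def write_edf(recording: Recording, path, sidecar: bool = True) -> Path:
    """Write a Recording to ``path`` as EDF with a JSON role sidecar."""
    path = Path(path)
    fs = recording.sample_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs  # 1-s records; trailing partials dropped
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s data record")
    n_ch = recording.data.shape[0]

    data = recording.data[:, : n_records * fs]
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-9)
    scale = _DIG_MAX / phys_max
    digital = np.round(data * scale[:, None]).astype("<i2")

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad(start.strftime("%d.%m.%y"), 8),
            _pad(start.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (n_ch + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    fields = [
        ("%s", 16, list(recording.channel_names)),
        ("%s", 80, ["" for _ in range(n_ch)]),            # transducer
        ("%s", 8, ["uV" for _ in range(n_ch)]),           # physical dimension
        ("%s", 8, [f"{-pm:.6g}"[:8] for pm in phys_max]),  # physical min
        ("%s", 8, [f"{pm:.6g}"[:8] for pm in phys_max]),   # physical max
        ("%s", 8, [str(_DIG_MIN)] * n_ch),
        ("%s", 8, [str(_DIG_MAX)] * n_ch),
        ("%s", 80, ["" for _ in range(n_ch)]),            # prefiltering
        ("%s", 8, [str(fs)] * n_ch),
        ("%s", 32, ["" for _ in range(n_ch)]),
    ]
    sig_header = b"".join(
        _pad(v, width) for _, width, values in fields for v in values
    )
    with open(path, "wb") as f:
        f.write(header + sig_header)
        # records: for each second, each channel's fs samples contiguously
        rec = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        f.write(np.ascontiguousarray(rec).tobytes())

    if sidecar:
        meta = {
            "channel_roles": dict(zip(recording.channel_names,
                                      recording.channel_roles)),
            "sample_rate": fs,
            "lights_on": list(recording.lights_on),
        }
        Path(f"{path}.json").write_text(json.dumps(meta, indent=1))
    return path


def _roles_from_labels(labels: list[str]) -> list[str]:
    roles = []
    for lab in labels:
        low = lab.lower()
        if "front" in low:
            roles.append("frontal")
        elif "par" in low:
            roles.append("parietal")
        elif "acc" in low:
            roles.append("accelerometer")
        else:
            raise ValueError(
                f"cannot infer channel roles from labels {labels!r}; "
                "provide a JSON sidecar with a 'channel_roles' map"
            )
    return roles


def read_recording(path) -> Recording:
    """Read an EDF file (plus optional JSON sidecar) into a Recording."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = (raw.get_data() * 1e6).astype(np.float32)  # mne scales uV -> V
    labels = list(raw.ch_names)

    sidecar = Path(f"{path}.json")
    lights_on = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        role_map = meta.get("channel_roles", {})
        try:
            roles = [role_map[lab] for lab in labels]
        except KeyError as e:
            raise ValueError(
                f"sidecar role map missing channel {e.args[0]!r}; labels: {labels}"
            ) from None
        if "lights_on" in meta:
            lights_on = tuple(meta["lights_on"])
        fs = float(meta.get("sample_rate", raw.info["sfreq"]))
    else:
        roles = _roles_from_labels(labels)
        fs = float(raw.info["sfreq"])

    return Recording(
        data=data,
        sample_rate=fs,
        channel_names=labels,
        channel_roles=roles,
        lights_on=lights_on,
        meta={"source": str(path)},
    )
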