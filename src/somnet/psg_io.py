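"""EDF(+) polysomnogram I/O, hypnogram handling and montage selection.

The reader/writer implement the 16-bit EDF and EDF+C subset of the format:
one-second data records, per-channel sampling rates, physical/digital
scaling, and (for EDF+) a ``EDF Annotations`` channel carrying time-stamped
annotation lists (TALs) used here to encode 30 s sleep-stage epochs.
Discontinuous (EDF+D) files are not supported.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
import re
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

AASM_STAGES = ("W", "N1", "N2", "N3", "R")
UNKNOWN = "UNKNOWN"
STAGE_VOCAB = AASM_STAGES + (UNKNOWN,)
STAGE_TO_INDEX = {s: i for i, s in enumerate(AASM_STAGES)}

RK_TO_AASM = {
    "W": "W",
    "S1": "N1",
    "S2": "N2",
    "S3": "N3",
    "S4": "N3",
    "REM": "R",
    "MT": UNKNOWN,
    "UNSCORED": UNKNOWN,
}

#: Annotation text used for stage epochs in EDF+ files (the convention most
#: sleep-lab exports follow), plus the bare tokens accepted on reading.
_STAGE_ANNOTATION = {s: f"Sleep stage {s}" for s in AASM_STAGES}
_STAGE_ANNOTATION[UNKNOWN] = "Sleep stage ?"
_ANNOTATION_TO_STAGE = {v: k for k, v in _STAGE_ANNOTATION.items()}
_ANNOTATION_TO_STAGE.update({s: s for s in STAGE_VOCAB})


class PSGError(Exception):
    """Base error for this module."""


class FormatError(PSGError):
    """Malformed or truncated EDF data."""


class ValidationError(PSGError):
    """Input violates a documented precondition."""


class MappingError(PSGError):
    """Stage label outside the declared vocabulary."""


class MontageError(PSGError):
    """Required signal roles missing from a recording."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Channel:
    label: str
    fs: float
    unit: str
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)


@dataclasses.dataclass
class Recording:
    """Multichannel signal container with per-channel sampling rates."""

    id: str
    channels: list[Channel]
    start_time: _dt.datetime = dataclasses.field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 23, 0, 0)
    )

    @property
    def duration(self) -> float:
        if not self.channels:
            return 0.0
        return max(len(c.samples) / c.fs for c in self.channels)

    def channel(self, label: str) -> Channel:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(label)

    def validate(self) -> None:
        if not self.channels:
            raise ValidationError("recording has no channels")
        dur = self.duration
        for c in self.channels:
            if c.fs <= 0:
                raise ValidationError(f"channel {c.label!r}: fs must be > 0")
            if abs(len(c.samples) - c.fs * dur) > c.fs * 1.0 + 1:
                raise ValidationError(
                    f"channel {c.label!r}: sample count inconsistent with duration"
                )


@dataclasses.dataclass
class Hypnogram:
    """Per-30-s-epoch stage labels with scheme provenance."""

    stages: list[str]
    source_scheme: str = "AASM"
    epoch_seconds: int = 30

    def __post_init__(self):
        if self.epoch_seconds != 30:
            raise ValidationError("epoch_seconds must be 30")
        if len(self.stages) < 1:
            raise ValidationError("hypnogram must contain at least one epoch")
        for s in self.stages:
            if s not in STAGE_VOCAB:
                raise MappingError(f"stage label {s!r} outside AASM vocabulary")

    def __len__(self):
        return len(self.stages)


@dataclasses.dataclass
class MontageSelection:
    eeg1: str
    eeg2: str
    emg: str
    eog: str
    ecg: Optional[str] = None

    def labels(self) -> list[str]:
        return [self.eeg1, self.eeg2, self.emg, self.eog]


# ---------------------------------------------------------------------------
# Stage vocabulary mapping
# ---------------------------------------------------------------------------

def map_stages_to_aasm(labels: Sequence[str], scheme: str) -> Hypnogram:
    """Map R&K or AASM stage tokens to the 5-stage AASM vocabulary.

    R&K S3 and S4 merge into N3; movement time (MT) and unscored epochs have
    no AASM counterpart and map to UNKNOWN (they are excluded downstream from
    training and agreement scoring).
    """
    scheme = scheme.upper()
    if scheme not in ("AASM", "RK"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    out = []
    for lab in labels:
        tok = str(lab).strip().upper()
        if scheme == "AASM":
            if tok not in STAGE_VOCAB:
                raise MappingError(f"label {lab!r} not in AASM vocabulary")
            out.append(tok)
        else:
            if tok not in RK_TO_AASM:
                raise MappingError(f"label {lab!r} not in R&K vocabulary")
            out.append(RK_TO_AASM[tok])
    return Hypnogram(stages=out, source_scheme=scheme if scheme == "AASM" else "RK")


# ---------------------------------------------------------------------------
# EDF(+) writing
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    b = s.encode("ascii", errors="replace")
    if len(b) > width:
        raise ValidationError(f"field {s!r} exceeds EDF width {width}")
    return b.ljust(width)


def _fmt_float(x: float, width: int = 8) -> bytes:
    for fmt in ("%g", "%.6g", "%.4g", "%.2f", "%.1f"):
        s = fmt % x
        if len(s) <= width:
            return s.encode("ascii").ljust(width)
    raise ValidationError(f"cannot encode {x} in {width} ascii chars")


def _stage_tals(hyp: Hypnogram) -> list[tuple[int, bytes]]:
    """(record_index, TAL bytes) for each 30 s stage annotation."""
    tals = []
    for k, stage in enumerate(hyp.stages):
        onset = k * hyp.epoch_seconds
        text = _STAGE_ANNOTATION[stage]
        tal = f"+{onset}\x15{hyp.epoch_seconds}\x14{text}\x14\x00".encode("ascii")
        tals.append((onset, tal))
    return tals


def write_edf(rec: Recording, hyp: Optional[Hypnogram], path) -> None:
    """Write ``rec`` (and optionally a hypnogram) as EDF / EDF+C.

    Uses one-second data records, so every channel must have an integer
    sampling rate.  When ``hyp`` is given the file is EDF+C and stages are
    stored as 30 s annotations at onsets 0, 30, 60, ...
    """
    rec.validate()
    path = Path(path)
    n_records = int(math.ceil(rec.duration))
    if n_records <= 0:
        raise ValidationError("recording is empty")
    for c in rec.channels:
        if abs(c.fs - round(c.fs)) > 1e-9:
            raise ValidationError(
                f"channel {c.label!r}: EDF writer requires integer Hz (got {c.fs})"
            )
        if len(c.label.encode("ascii", errors="replace")) > 16:
            raise ValidationError(f"channel label {c.label!r} longer than 16 chars")

    is_plus = hyp is not None
    tals = _stage_tals(hyp) if is_plus else []
    # Annotation channel capacity (bytes per record): timekeeping TAL plus
    # any stage TAL whose onset falls in that record.
    ann_bytes_per_rec = 0
    if is_plus:
        per_rec: dict[int, int] = {}
        for onset, tal in tals:
            r = min(onset, n_records - 1)
            per_rec[r] = per_rec.get(r, 0) + len(tal)
        base = len(b"+%d\x14\x14\x00" % (n_records,)) + 8
        ann_bytes_per_rec = base + max(per_rec.values(), default=0)
        if ann_bytes_per_rec % 2:
            ann_bytes_per_rec += 1

    chans = list(rec.channels)
    n_sig = len(chans) + (1 if is_plus else 0)

    # Per-channel scaling.
    scaling = []
    for c in chans:
        x = c.samples
        pmin = float(np.min(x)) if x.size else -1.0
        pmax = float(np.max(x)) if x.size else 1.0
        if pmax - pmin < 1e-12:
            pmin, pmax = pmin - 1.0, pmax + 1.0
        scaling.append((pmin, pmax))

    hdr = bytearray()
    hdr += _ascii_field("0", 8)
    hdr += _ascii_field("X X X X", 80)
    hdr += _ascii_field(f"Startdate X X X X {rec.id}"[:80], 80)
    hdr += _ascii_field(rec.start_time.strftime("%d.%m.%y"), 8)
    hdr += _ascii_field(rec.start_time.strftime("%H.%M.%S"), 8)
    header_bytes = 256 * (1 + n_sig)
    hdr += _ascii_field(header_bytes, 8)
    hdr += _ascii_field("EDF+C" if is_plus else "", 44)
    hdr += _ascii_field(n_records, 8)
    hdr += _ascii_field(1, 8)
    hdr += _ascii_field(n_sig, 4)

    labels = [c.label for c in chans] + (["EDF Annotations"] if is_plus else [])
    for lab in labels:
        hdr += _ascii_field(lab, 16)
    for _ in labels:
        hdr += _ascii_field("", 80)  # transducer
    units = [c.unit for c in chans] + ([""] if is_plus else [])
    for u in units:
        hdr += _ascii_field(u, 8)
    for i, _ in enumerate(labels):
        pmin = scaling[i][0] if i < len(chans) else -1
        hdr += _fmt_float(pmin)
    for i, _ in enumerate(labels):
        pmax = scaling[i][1] if i < len(chans) else 1
        hdr += _fmt_float(pmax)
    for _ in labels:
        hdr += _ascii_field(-32768, 8)
    for _ in labels:
        hdr += _ascii_field(32767, 8)
    for _ in labels:
        hdr += _ascii_field("", 80)  # prefiltering
    ns_list = [int(round(c.fs)) for c in chans] + (
        [ann_bytes_per_rec // 2] if is_plus else []
    )
    for ns in ns_list:
        hdr += _ascii_field(ns, 8)
    for _ in labels:
        hdr += _ascii_field("", 32)

    # Digitize signals once, padded to whole records.
    digitized = []
    for c, (pmin, pmax) in zip(chans, scaling):
        ns = int(round(c.fs))
        total = ns * n_records
        x = np.zeros(total, dtype=np.float64)
        x[: len(c.samples)] = c.samples
        dig = np.round(
            (x - pmin) / (pmax - pmin) * 65535.0 - 32768.0
        ).clip(-32768, 32767).astype("<i2")
        digitized.append(dig.reshape(n_records, ns))

    stage_by_record: dict[int, list[bytes]] = {}
    for onset, tal in tals:
        r = min(onset, n_records - 1)
        stage_by_record.setdefault(r, []).append(tal)

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        for r in range(n_records):
            for dig in digitized:
                fh.write(dig[r].tobytes())
            if is_plus:
                buf = b"+%d\x14\x14\x00" % r
                for tal in stage_by_record.get(r, []):
                    buf += tal
                if len(buf) > ann_bytes_per_rec:
                    raise ValidationError("annotation record overflow")
                fh.write(buf.ljust(ann_bytes_per_rec, b"\x00"))


# ---------------------------------------------------------------------------
# EDF(+) reading
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EdfAnnotation:
    onset: float
    duration: Optional[float]
    text: str


def _parse_tals(raw: bytes) -> list[EdfAnnotation]:
    out = []
    for tal in raw.split(b"\x00"):
        if not tal:
            continue
        head, *texts = tal.split(b"\x14")
        if b"\x15" in head:
            onset_b, dur_b = head.split(b"\x15", 1)
            duration = float(dur_b)
        else:
            onset_b, duration = head, None
        try:
            onset = float(onset_b)
        except ValueError:
            continue
        for t in texts:
            if t:
                out.append(EdfAnnotation(onset, duration, t.decode("utf-8", "replace")))
    return out


def read_edf(path) -> tuple[Recording, list[EdfAnnotation]]:
    """Read an EDF or EDF+C file.

    Returns the :class:`Recording` (signal channels only, native per-channel
    sampling rates and physical units preserved) and the annotation list,
    which is empty for plain EDF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = path.read_bytes()
    if len(data) < 256:
        raise FormatError("file shorter than EDF header")
    try:
        n_sig = int(data[252:256].decode("ascii").strip())
        header_bytes = int(data[184:192].decode("ascii").strip())
        n_records = int(data[236:244].decode("ascii").strip())
        record_dur = float(data[244:252].decode("ascii").strip())
        reserved = data[192:236].decode("ascii").strip()
        date_s = data[168:176].decode("ascii").strip()
        time_s = data[176:184].decode("ascii").strip()
    except (ValueError, UnicodeDecodeError) as exc:
        raise FormatError(f"malformed EDF header: {exc}") from exc
    if reserved.startswith("EDF+D"):
        raise FormatError("discontinuous EDF+D files are not supported")
    if n_sig <= 0 or header_bytes != 256 * (1 + n_sig):
        raise FormatError("inconsistent EDF header sizes")
    if len(data) < header_bytes:
        raise FormatError("truncated EDF header")

    def fields(offset, width):
        base = 256 + offset * n_sig
        return [
            data[base + i * width : base + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(n_sig)
        ]

    # Signal header block layout: label 16, transducer 80, dim 8, phys 8+8,
    # dig 8+8, prefilter 80, ns 8, reserved 32 (offsets in bytes per field).
    off = 0
    labels = fields(off, 16); off += 16
    off += 80  # transducer
    units = fields(off, 8); off += 8
    try:
        pmins = [float(v) for v in fields(off, 8)]; off += 8
        pmaxs = [float(v) for v in fields(off, 8)]; off += 8
        dmins = [float(v) for v in fields(off, 8)]; off += 8
        dmaxs = [float(v) for v in fields(off, 8)]; off += 8
        off += 80  # prefiltering
        ns_list = [int(v) for v in fields(off, 8)]
    except ValueError as exc:
        raise FormatError(f"malformed EDF signal header: {exc}") from exc

    rec_size = 2 * sum(ns_list)
    body = data[header_bytes:]
    if n_records < 0:  # -1 allowed by the standard: infer from size
        n_records = len(body) // rec_size
    if len(body) < rec_size * n_records:
        raise FormatError("truncated EDF data records")

    try:
        start = _dt.datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
    except ValueError:
        start = _dt.datetime(2000, 1, 1)

    raw = np.frombuffer(body[: rec_size * n_records], dtype="<i2")
    raw = raw.reshape(n_records, rec_size // 2)
    bounds = np.cumsum([0] + ns_list)

    channels: list[Channel] = []
    annotations: list[EdfAnnotation] = []
    for i, lab in enumerate(labels):
        chunk = raw[:, bounds[i] : bounds[i + 1]]
        if lab == "EDF Annotations":
            annotations = _parse_tals(chunk.astype("<i2").tobytes())
            continue
        dmin, dmax = dmins[i], dmaxs[i]
        pmin, pmax = pmins[i], pmaxs[i]
        if dmax == dmin:
            raise FormatError(f"channel {lab!r}: degenerate digital range")
        gain = (pmax - pmin) / (dmax - dmin)
        phys = (chunk.astype(np.float64).ravel() - dmin) * gain + pmin
        channels.append(Channel(lab, ns_list[i] / record_dur, units[i], phys))

    rec_id = path.stem
    m = re.search(r"Startdate .*? .*? .*? .*? (\S+)", data[88:168].decode("ascii", "replace"))
    if m:
        rec_id = m.group(1)
    return Recording(id=rec_id, channels=channels, start_time=start), annotations


def hypnogram_from_annotations(annotations: Sequence[EdfAnnotation]) -> Hypnogram:
    """Rebuild the per-epoch hypnogram from EDF+ stage annotations."""
    stage_anns = [
        a for a in annotations if a.text in _ANNOTATION_TO_STAGE and a.duration
    ]
    if not stage_anns:
        raise ValidationError("no stage annotations found")
    stage_anns.sort(key=lambda a: a.onset)
    n_epochs = int(round(stage_anns[-1].onset / 30.0)) + 1
    stages = [UNKNOWN] * n_epochs
    for a in stage_anns:
        k = int(round(a.onset / 30.0))
        if 0 <= k < n_epochs:
            stages[k] = _ANNOTATION_TO_STAGE[a.text]
    return Hypnogram(stages=stages)


# ---------------------------------------------------------------------------
# Plain-text hypnograms (one stage token per line; header lines ignored)
# ---------------------------------------------------------------------------

def read_hypnogram_text(path, scheme: str = "AASM") -> Hypnogram:
    tokens = []
    for line in Path(path).read_text().splitlines():
        tok = line.strip()
        if not tok or tok.startswith("#"):
            continue
        tokens.append(tok)
    return map_stages_to_aasm(tokens, scheme)


def write_hypnogram_text(hyp: Hypnogram, path) -> None:
    Path(path).write_text("\n".join(hyp.stages) + "\n")


# ---------------------------------------------------------------------------
# Montage selection
# ---------------------------------------------------------------------------

#: Ordered, case-insensitive label patterns per signal role.  EEG patterns
#: are tried in order (central derivations first, frontal as backup, any
#: EEG-looking label last), mirroring common clinical montage conventions.
DEFAULT_PREFERENCES: dict[str, list[str]] = {
    "eeg": [r"C4", r"C3", r"F4", r"F3", r"EEG", r"\b(?:Fp?z|Pz|Cz|Oz|O[12]|P[34])\b"],
    "emg": [r"CHIN", r"EMG"],
    "eog": [r"HORIZ", r"\bE[12]\b", r"EOG", r"LOC|ROC"],
    "ecg": [r"ECG", r"EKG"],
}


def _match_role(label: str, patterns: list[str]) -> bool:
    return any(re.search(p, label, flags=re.IGNORECASE) for p in patterns)


def select_montage(
    rec: Recording, preferences: Optional[dict[str, list[str]]] = None
) -> MontageSelection:
    """Pick the 2xEEG + EMG + EOG (+ optional ECG) input montage.

    Central EEG derivations are preferred, frontal as backup, otherwise the
    first two EEG-looking channels; horizontal EOG derivations are preferred
    over vertical ones.
    """
    prefs = {**DEFAULT_PREFERENCES, **(preferences or {})}
    labels = [c.label for c in rec.channels]

    def claim(role: str, pool: list[str]) -> Optional[str]:
        for pat in prefs[role]:
            for lab in pool:
                if re.search(pat, lab, flags=re.IGNORECASE):
                    return lab
        return None

    pool = list(labels)
    ecg = claim("ecg", pool)
    if ecg:
        pool.remove(ecg)
    # EMG/EOG claimed before EEG so that e.g. "E1-M2" is not mistaken for EEG.
    emg = claim("emg", pool)
    if emg:
        pool.remove(emg)
    eog = claim("eog", pool)
    if eog:
        pool.remove(eog)

    eeg_pool = [
        lab
        for lab in pool
        if _match_role(lab, prefs["eeg"])
        and not _match_role(lab, prefs["emg"] + prefs["eog"] + prefs["ecg"])
    ]
    eeg1 = claim("eeg", eeg_pool)
    if eeg1:
        eeg_pool = [l for l in eeg_pool if l != eeg1]
    eeg2 = claim("eeg", eeg_pool)

    missing = [
        role
        for role, val in (("eeg1", eeg1), ("eeg2", eeg2), ("emg", emg), ("eog", eog))
        if val is None
    ]
    if missing:
        raise MontageError(f"missing mandatory montage roles: {', '.join(missing)}")
    return MontageSelection(eeg1=eeg1, eeg2=eeg2, emg=emg, eog=eog, ecg=ecg)
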