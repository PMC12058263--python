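"""Read and write centroided LC-MS runs as mzML 1.1.

The in-memory model is deliberately small: a ``Run`` is an ordered list of
centroided MS1 ``Spectrum`` objects plus a little metadata (sample label,
polarity, acquisition m/z window).  Retention times are minutes
throughout.

The mzML layer is self-contained: spectra are serialized with
uncompressed little-endian 64-bit float binary arrays and the standard
PSI-MS controlled-vocabulary terms, and parsed back with the stdlib XML
parser.  Profile-mode spectra are rejected loudly — centroiding raw
vendor data is out of scope, and silently treating profile points as
centroids would corrupt every downstream area.
"""

from __future__ import annotations

import base64
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Spectrum", "Run", "read_run", "write_run"]

_NS = "http://psi.hupo.org/ms/mzml"

# accession -> meaning, for the few CV terms this reader interprets
_ACC_MS1 = "MS:1000511"          # ms level
_ACC_CENTROID = "MS:1000127"     # centroid spectrum
_ACC_PROFILE = "MS:1000128"      # profile spectrum
_ACC_RT = "MS:1000016"           # scan start time
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_LO = "MS:1000501"           # scan window lower limit
_ACC_HI = "MS:1000500"           # scan window upper limit
_ACC_NEG = "MS:1000129"          # negative scan


@dataclass
class Spectrum:
    """One centroided MS1 scan: retention time (min) plus sorted centroids."""

    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-D arrays")
        if self.retention_time < 0:
            raise ValueError("retention_time must be >= 0")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("centroid m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class Run:
    """An acquisition: MS1 spectra in retention-time order plus metadata."""

    spectra: list[Spectrum]
    label: str = "run"
    polarity: str = "positive"
    mz_range: tuple[float, float] = (100.0, 3000.0)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("a Run needs at least one spectrum")
        rts = [s.retention_time for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be in non-decreasing retention-time order")

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([s.retention_time for s in self.spectra])

    @property
    def total_ion_current(self) -> float:
        return float(sum(s.intensity.sum() for s in self.spectra))


def _b64(a: np.ndarray) -> str:
    return base64.b64encode(np.asarray(a, dtype="<f8").tobytes()).decode("ascii")


def _cv(acc: str, name: str, value: str = "", unit: str = "") -> str:
    return f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value="{value}"{unit}/>'


_MIN_UNIT = ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'
_MZ_UNIT = ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'


def write_run(run: Run, path: str | Path) -> None:
    """Serialize a Run to mzML 1.1 (uncompressed 64-bit float arrays).

    Output is deterministic: identical runs produce byte-identical files.
    """
    lo, hi = run.mz_range
    pol = ("MS:1000130", "positive scan") if run.polarity == "positive" \
        else (_ACC_NEG, "negative scan")
    parts: list[str] = []
    parts.append('<?xml version="1.0" encoding="utf-8"?>')
    parts.append(f'<mzML xmlns="{_NS}" version="1.1.0">')
    parts.append(
        '<cvList count="2">'
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/'
        'bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>"
    )
    parts.append(
        "<fileDescription><fileContent>"
        + _cv("MS:1000579", "MS1 spectrum")
        + _cv(_ACC_CENTROID, "centroid spectrum")
        + "</fileContent></fileDescription>"
    )
    parts.append(f'<run id="{run.label}">')
    parts.append(f'<spectrumList count="{len(run.spectra)}">')
    for i, s in enumerate(run.spectra):
        mz64, it64 = _b64(s.mz), _b64(s.intensity)
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{s.mz.size}">'
            + _cv(_ACC_MS1, "ms level", "1")
            + _cv(_ACC_CENTROID, "centroid spectrum")
            + _cv(*pol)
            + '<scanList count="1"><scan>'
            + _cv(_ACC_RT, "scan start time", repr(float(s.retention_time)), _MIN_UNIT)
            + '<scanWindowList count="1"><scanWindow>'
            + _cv(_ACC_LO, "scan window lower limit", repr(float(lo)), _MZ_UNIT)
            + _cv(_ACC_HI, "scan window upper limit", repr(float(hi)), _MZ_UNIT)
            + "</scanWindow></scanWindowList></scan></scanList>"
            + '<binaryDataArrayList count="2">'
            + f'<binaryDataArray encodedLength="{len(mz64)}">'
            + _cv("MS:1000523", "64-bit float")
            + _cv("MS:1000576", "no compression")
            + _cv(_ACC_MZ_ARRAY, "m/z array", "", _MZ_UNIT)
            + f"<binary>{mz64}</binary></binaryDataArray>"
            + f'<binaryDataArray encodedLength="{len(it64)}">'
            + _cv("MS:1000523", "64-bit float")
            + _cv("MS:1000576", "no compression")
            + _cv(_ACC_INT_ARRAY, "intensity array")
            + f"<binary>{it64}</binary></binaryDataArray>"
            + "</binaryDataArrayList></spectrum>"
        )
    parts.append("</spectrumList></run></mzML>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")


def _accessions(elem: ET.Element) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in elem.iter(f"{{{_NS}}}cvParam")
    }


def read_run(path: str | Path) -> Run:
    """Parse an mzML file into a Run of centroided MS1 spectra.

    Raises ``ValueError`` for profile-mode data or malformed documents.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"malformed mzML: {exc}") from exc
    root = tree.getroot()
    # tolerate an indexedmzML wrapper
    mzml = root if root.tag == f"{{{_NS}}}mzML" else root.find(f"{{{_NS}}}mzML")
    if mzml is None:
        raise ValueError("not an mzML document")
    run_el = mzml.find(f"{{{_NS}}}run")
    if run_el is None:
        raise ValueError("mzML document has no <run>")

    spectra: list[Spectrum] = []
    polarity = "positive"
    mz_range = (100.0, 3000.0)
    for sp in run_el.iter(f"{{{_NS}}}spectrum"):
        acc = _accessions(sp)
        if acc.get(_ACC_MS1, "1") != "1":
            continue
        if _ACC_PROFILE in acc:
            raise ValueError(
                "profile-mode spectrum encountered; this pipeline consumes "
                "centroided data only — convert/centroid upstream"
            )
        if _ACC_NEG in acc:
            polarity = "negative"
        rt = float(acc.get(_ACC_RT, "0"))
        if _ACC_LO in acc and _ACC_HI in acc:
            mz_range = (float(acc[_ACC_LO]), float(acc[_ACC_HI]))
        arrays: dict[str, np.ndarray] = {}
        for bda in sp.iter(f"{{{_NS}}}binaryDataArray"):
            bacc = _accessions(bda)
            if "MS:1000523" not in bacc:
                raise ValueError("only 64-bit float arrays are supported")
            if "MS:1000576" not in bacc:
                raise ValueError("only uncompressed binary arrays are supported")
            binary = bda.find(f"{{{_NS}}}binary")
            raw = base64.b64decode(binary.text or "")
            data = np.frombuffer(raw, dtype="<f8")
            if _ACC_MZ_ARRAY in bacc:
                arrays["mz"] = data
            elif _ACC_INT_ARRAY in bacc:
                arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError("spectrum lacks m/z or intensity array")
        spectra.append(Spectrum(rt, arrays["mz"].copy(), arrays["intensity"].copy()))
    if not spectra:
        raise ValueError("mzML document contains no MS1 spectra")
    return Run(spectra, label=run_el.get("id", path.stem), polarity=polarity,
               mz_range=mz_range)
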