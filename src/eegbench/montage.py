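"""Standard 10-20 scalp montage: canonical labels and unit-sphere positions.

All devices in a multi-device study are mapped onto the 19 canonical 10-20
positions so that spectra, evoked responses and cluster statistics are
comparable across hardware. Positions come from mne's ``standard_1020``
template and are normalized to the unit sphere for interpolation and
adjacency computations.
"""

from __future__ import annotations

import functools

import numpy as np

#: Canonical 19-channel 10-20 montage (modern T7/T8/P7/P8 naming).
STANDARD_1020: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Aliases used by older nomenclature / some vendors.
LABEL_ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

FRONTAL = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8")
TEMPORAL = ("T7", "T8", "F7", "F8")
POSTERIOR = ("P7", "P3", "Pz", "P4", "P8", "O1", "O2")

#: Posterior/central region of interest shared by all devices.
VISUAL_ROI = ("O1", "O2", "P3", "Pz", "P4", "C3", "Cz", "C4")

HEAD_RADIUS_M = 0.095


def canonical_label(label: str) -> str:
    """Map a channel label onto canonical montage naming.

    The 19 canonical 10-20 labels (and their T3/T4/T5/T6 aliases) are the
    primary namespace; extended 10-10 labels present in the standard
    template (higher-density research caps) are also accepted.
    """
    label = label.strip()
    for cand in (label, label.capitalize(), label.upper()):
        if cand in STANDARD_1020:
            return cand
        if cand in LABEL_ALIASES:
            return LABEL_ALIASES[cand]
    lower = {l.lower(): l for l in _template_positions()}
    if label.lower() in lower:
        return lower[label.lower()]
    raise KeyError(f"channel label {label!r} is not a 10-20/10-10 montage label")


@functools.lru_cache(maxsize=1)
def _template_positions() -> dict[str, np.ndarray]:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    out = {}
    for label, p in pos.items():
        p = np.asarray(p, dtype=float)
        out[label] = p / np.linalg.norm(p)
    return out


def positions(labels=STANDARD_1020) -> np.ndarray:
    """Unit-sphere 3D coordinates for the requested 10-20 labels.

    Returns an ``(n, 3)`` array in the order of ``labels``.
    """
    tpl = _template_positions()
    return np.array([tpl[canonical_label(l)] for l in labels], dtype=float)


def make_dig_montage(labels):
    """mne DigMontage for the given labels (head-sized sphere, meters)."""
    import mne

    tpl = _template_positions()
    ch_pos = {canonical_label(l): tpl[canonical_label(l)] * HEAD_RADIUS_M for l in labels}
    return mne.channels.make_dig_montage(ch_pos=ch_pos, coord_frame="head")


def validate_labels(labels) -> list[str]:
    """Canonicalize a channel list; raise listing any non-montage labels."""
    good, bad = [], []
    for l in labels:
        try:
            good.append(canonical_label(l))
        except KeyError:
            bad.append(l)
    if bad:
        raise ValueError(f"unknown channel labels (not in 10-20 montage): {bad}")
    return good
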