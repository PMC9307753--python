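"""Reference metadata of the public deposit this package targets.

The SingleWordProductionDutch-iBIDS dataset (DOI 10.17605/OSF.IO/NRGX6)
contains 10 participants reading 100 prompted words each. Its published
montage table lists, per participant, the number of implanted sEEG
electrode contacts and the number actually recorded (the recorded count
excludes the common white-matter reference contact). These counts are
carried here so montage arithmetic can be checked without the deposit.
"""

from __future__ import annotations

__all__ = [
    "PARTICIPANTS",
    "IMPLANTED_CONTACTS",
    "RECORDED_CONTACTS",
    "total_implanted",
    "total_recorded",
]

PARTICIPANTS = tuple(f"sub-{i:02d}" for i in range(1, 11))

IMPLANTED_CONTACTS = {
    "sub-01": 133,
    "sub-02": 234,
    "sub-03": 184,
    "sub-04": 117,
    "sub-05": 61,
    "sub-06": 155,
    "sub-07": 134,
    "sub-08": 56,
    "sub-09": 119,
    "sub-10": 124,
}

RECORDED_CONTACTS = {
    "sub-01": 127,
    "sub-02": 127,
    "sub-03": 127,
    "sub-04": 115,
    "sub-05": 60,
    "sub-06": 127,
    "sub-07": 127,
    "sub-08": 54,
    "sub-09": 117,
    "sub-10": 122,
}


def total_implanted() -> int:
    """Total implanted contacts across all participants."""
    return sum(IMPLANTED_CONTACTS[p] for p in PARTICIPANTS)


def total_recorded() -> int:
    """Total recorded contacts across all participants."""
    return sum(RECORDED_CONTACTS[p] for p in PARTICIPANTS)
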