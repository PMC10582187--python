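"""Per-frame category alphabets for 1-3 color trace classification.

Every frame of a trajectory carries exactly one label.  Three labels are
trace-global junk categories (``noisy``, ``artifact``, ``aggregate``); the
remaining labels enumerate which dyes are still photoactive in that frame,
with the all-dyes-active combination split into a *dynamic* and a *static*
variant.  The size of the alphabet therefore depends on the modality: more
dyes means more photoactive subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MODALITIES = ("1c", "2c", "2c_alex", "3c_alex")

#: channel names, in storage order, per modality
CHANNELS = {
    "1c": ("DexDem",),
    "2c": ("DexDem", "DexAem"),
    "2c_alex": ("DexDem", "DexAem", "AexAem"),
    "3c_alex": ("BexBem", "BexYem", "BexRem", "YexYem", "YexRem", "RexRem"),
}

#: dyes present per modality
DYES = {
    "1c": ("D",),
    "2c": ("D", "A"),
    "2c_alex": ("D", "A"),
    "3c_alex": ("B", "Y", "R"),
}

#: FRET pairs per modality (donor+acceptor naming)
PAIRS = {
    "1c": (),
    "2c": ("DA",),
    "2c_alex": ("DA",),
    "3c_alex": ("BY", "BR", "YR"),
}

#: channel indices carrying kinetic information (fed to state classifiers).
#: The acceptor signal after direct acceptor excitation is constant while the
#: acceptor is photoactive and carries no kinetic information, so it is
#: excluded.
KINETIC_CHANNELS = {
    "1c": (0,),
    "2c": (0, 1),
    "2c_alex": (0, 1),
    "3c_alex": (0, 1, 2, 3, 4),
}

JUNK_LABELS = ("noisy", "artifact", "aggregate")
BLEACHED_LABEL = "bleached"


def _active_set_labels(dyes: tuple[str, ...]) -> list[str]:
    """Labels for every photoactive dye subset, all-active split dyn/static."""
    names = "".join(dyes)
    labels = [f"{names}-dynamic", f"{names}-static"]
    # proper nonempty subsets, largest first, preserving dye order
    n = len(dyes)
    for size in range(n - 1, 0, -1):
        from itertools import combinations

        for combo in combinations(dyes, size):
            labels.append("".join(combo) if size > 1 else f"{combo[0]}-only")
    labels.append(BLEACHED_LABEL)
    return labels


@dataclass(frozen=True)
class CategoryAlphabet:
    """Label set for the per-frame trace classifier of one modality."""

    modality: str
    labels: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        labels = tuple(_active_set_labels(DYES[self.modality])) + JUNK_LABELS
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    @property
    def dynamic_label(self) -> str:
        return self.labels[0]

    @property
    def static_label(self) -> str:
        return self.labels[1]

    @property
    def all_active_labels(self) -> tuple[str, ...]:
        return self.labels[:2]

    def is_junk(self, label: str) -> bool:
        return label in JUNK_LABELS

    def active_dyes(self, label: str) -> frozenset[str]:
        """Dyes photoactive under a label; junk labels report all dyes."""
        dyes = DYES[self.modality]
        if label in JUNK_LABELS:
            return frozenset(dyes)
        if label == BLEACHED_LABEL:
            return frozenset()
        if label in self.all_active_labels:
            return frozenset(dyes)
        stem = label.replace("-only", "")
        return frozenset(d for d in dyes if d in stem)

    def label_for(self, active: frozenset[str], dynamic: bool) -> str:
        """Label for a set of photoactive dyes."""
        dyes = DYES[self.modality]
        active = frozenset(active)
        if active == frozenset(dyes):
            return self.dynamic_label if dynamic else self.static_label
        if not active:
            return BLEACHED_LABEL
        stem = "".join(d for d in dyes if d in active)
        return stem if len(active) > 1 else f"{stem}-only"


def n_channels(modality: str) -> int:
    return len(CHANNELS[modality])
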