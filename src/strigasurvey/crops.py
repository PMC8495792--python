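"""Crop name registry for the mid-west Madagascar rice--maize system.

Crop labels follow the conventions of the field survey they model:

* Rice varieties are written ``rice-<VARIETY>`` (e.g. ``rice-B22``,
  ``rice-NERICA4``); the base crop is ``rice`` but distinct varieties are
  treated as distinct crops when counting rotation diversity, because
  variety choice is itself a management decision with a measurable effect
  on *Striga* density.
* Mixed plantings recorded as a single season entry keep their combined
  label (``maize/manioc``); :func:`constituents` splits them back into
  individual crops where a per-crop view is needed.
* ``fallow`` is a valid land-use label and participates in rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field


FALLOW = "fallow"

DEFAULT_CEREALS = frozenset({"rice", "maize"})

# Mimosa diplotricha is incidental rather than planted, but is an
# N-enriching green manure and is scored with the legumes.
DEFAULT_LEGUMES = frozenset(
    {
        "groundnut",
        "soybean",
        "bambara groundnut",
        "cowpea",
        "ricebean",
        "common bean",
        "mung bean",
        "mimosa",
        "stylosanthes",
        "mucuna",
    }
)

DEFAULT_OTHER = frozenset(
    {"manioc", "sweet potato", "onion", "gourd", "taro", "other", FALLOW}
)


def constituents(label: str) -> list[str]:
    """Split a season label into its constituent crop names.

    ``"maize/manioc"`` -> ``["maize", "manioc"]``; a plain label is
    returned as a single-element list. Empty parts are dropped.
    """
    return [part.strip() for part in str(label).split("/") if part.strip()]


def base_crop(name: str) -> str:
    """Base crop of a single (non-mixed) label: ``rice-B22`` -> ``rice``."""
    return name.split("-", 1)[0].strip().lower()


@dataclass(frozen=True)
class CropRegistry:
    """Known crop names partitioned into cereals, legumes and other uses.

    Membership tests operate on base crops, so every rice variety is a
    cereal while remaining a distinct label for diversity counting.
    """

    cereals: frozenset[str] = DEFAULT_CEREALS
    legumes: frozenset[str] = DEFAULT_LEGUMES
    other: frozenset[str] = DEFAULT_OTHER
    fallow_label: str = FALLOW

    @property
    def known_bases(self) -> frozenset[str]:
        return self.cereals | self.legumes | self.other | {self.fallow_label}

    def is_known(self, label: str) -> bool:
        return all(base_crop(c) in self.known_bases for c in constituents(label))

    def unknown_names(self, label: str) -> list[str]:
        return [c for c in constituents(label) if base_crop(c) not in self.known_bases]

    def is_cereal(self, label: str) -> bool:
        """True if any constituent of the label is a cereal crop."""
        return any(base_crop(c) in self.cereals for c in constituents(label))

    def is_legume(self, label: str) -> bool:
        return any(base_crop(c) in self.legumes for c in constituents(label))

    def is_fallow(self, label: str) -> bool:
        return any(base_crop(c) == self.fallow_label for c in constituents(label))


DEFAULT_REGISTRY = CropRegistry()
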