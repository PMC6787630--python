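"""Interferon-stimulated gene (ISG) panel definition.

The default panel is the six-gene whole-blood set widely used to screen for
type I interferonopathies (IFI27, IFI44L, IFIT1, ISG15, RSAD2, SIGLEC1),
normalized against the housekeeping genes HPRT1 and G6PD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

DEFAULT_TARGETS: tuple[str, ...] = (
    "IFI27",
    "IFI44L",
    "IFIT1",
    "ISG15",
    "RSAD2",
    "SIGLEC1",
)
DEFAULT_HOUSEKEEPERS: tuple[str, ...] = ("HPRT1", "G6PD")


@dataclass(frozen=True)
class GenePanel:
    """A qPCR/RNA-seq gene panel: target ISGs plus housekeeping references.

    Parameters
    ----------
    targets
        Ordered ISG symbols whose fold changes enter the IFN score.
    housekeepers
        Reference genes used for within-sample normalization (ΔCt).
    min_genes_for_score
        Minimum number of target genes with a measurable fold change for a
        sample's median score to be reported; samples below it get a missing
        score rather than a score computed from too few genes.
    """

    targets: tuple[str, ...] = DEFAULT_TARGETS
    housekeepers: tuple[str, ...] = DEFAULT_HOUSEKEEPERS
    min_genes_for_score: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "housekeepers", tuple(self.housekeepers))
        if len(self.targets) < 1 or len(self.housekeepers) < 1:
            raise ValidationError("panel needs at least one target and one housekeeper")
        overlap = set(self.targets) & set(self.housekeepers)
        if overlap:
            raise ValidationError(
                f"targets and housekeepers must be disjoint; both contain {sorted(overlap)}"
            )
        if len(set(self.targets)) != len(self.targets):
            raise ValidationError("duplicate target symbols")
        if len(set(self.housekeepers)) != len(self.housekeepers):
            raise ValidationError("duplicate housekeeper symbols")
        if not 1 <= self.min_genes_for_score <= len(self.targets):
            raise ValidationError(
                "min_genes_for_score must be between 1 and the number of targets"
            )

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.targets + self.housekeepers


DEFAULT_PANEL = GenePanel()
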