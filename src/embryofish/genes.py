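"""Gene models of the mesodermal Dorsal targets.

Lengths and intron spans drive the elongation / intron-delay simulation:
*T48* is 29 kb with ~25 kb of intron, *mist* 9.3 kb, *twi* a short 2.2 kb
gene, all transcribed at the canonical ~2 kb/min Pol II elongation rate.
Probe regions are kb intervals along the transcription unit and define
when a 5', intron or 3' smFISH probe first sees signal at a locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GeneModel", "T48", "T48_CDNA", "MIST", "TWI"]

DEFAULT_ELONGATION_RATE = 2.0  # kb/min


@dataclass(frozen=True)
class GeneModel:
    """Transcription-unit geometry and elongation rate of one gene.

    ``length_kb`` is the full transcription-unit length, ``intron_kb``
    the total intron span removed by splicing (exonic transcript length
    is ``length_kb - intron_kb``). ``probes`` maps probe names to
    ``(start, end)`` kb intervals along the unit.
    """

    name: str
    length_kb: float
    intron_kb: float = 0.0
    probes: dict[str, tuple[float, float]] = field(default_factory=dict)
    elongation_rate: float = DEFAULT_ELONGATION_RATE  # kb/min

    def __post_init__(self) -> None:
        if self.length_kb < 0:
            raise ValueError("gene length must be non-negative")
        if not 0 <= self.intron_kb <= self.length_kb:
            raise ValueError("intron span must lie within the gene length")
        if self.elongation_rate <= 0:
            raise ValueError("elongation rate must be positive")
        for name, (start, end) in self.probes.items():
            if not (0 <= start <= end <= self.length_kb):
                raise ValueError(f"probe region {name!r} outside [0, length]")

    @property
    def exonic_kb(self) -> float:
        return self.length_kb - self.intron_kb

    def intronless(self, name: str | None = None) -> "GeneModel":
        """The cDNA version of this gene: exons only, probes remapped.

        Probe intervals that fall entirely inside the intron are dropped;
        the 3' probe of the endogenous gene maps onto the 3' end of the
        cDNA.
        """
        new_probes: dict[str, tuple[float, float]] = {}
        intron_start = self.probes.get("intron", (self.exonic_kb, self.exonic_kb))[0]
        for pname, (start, end) in self.probes.items():
            if pname == "intron":
                continue
            if end <= intron_start:  # 5' exon: unchanged coordinates
                new_probes[pname] = (start, end)
            else:  # 3' exon: shift left by the intron span
                new_probes[pname] = (
                    max(start - self.intron_kb, 0.0),
                    end - self.intron_kb,
                )
        return GeneModel(
            name=name or f"{self.name}-cDNA",
            length_kb=self.exonic_kb,
            intron_kb=0.0,
            probes=new_probes,
            elongation_rate=self.elongation_rate,
        )


#: T48: 29 kb transcription unit dominated by ~25 kb of intron; the short
#: 5' exon carries the 5' probe, the 3' exon the 3' probe.
T48 = GeneModel(
    name="T48",
    length_kb=29.0,
    intron_kb=25.0,
    probes={"5p": (0.0, 2.0), "intron": (2.0, 27.0), "3p": (27.0, 29.0)},
)

#: Intronless T48 cDNA transgene (exonic length only, 3' probe retained).
T48_CDNA = T48.intronless()

#: mist: a comparatively short 9.3 kb gene.
MIST = GeneModel(name="mist", length_kb=9.3, probes={"5p": (0.0, 2.0)})

#: twi: 2.2 kb; completes transcription with negligible delay.
TWI = GeneModel(name="twi", length_kb=2.2, probes={"full": (0.0, 2.2)})
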