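"""Synthetic S8 and I9 anchor segments shipped with the package.

These two fixed segments are *synthetic* stand-ins for the conserved cores
of the subtilase peptidase (S8) domain and the I9 prodomain.  They let the
whole pipeline — architecture annotation, completeness filtering, junction
calling, residue-331 mapping — run and be tested end to end without any
external reference sequence, while real references (e.g. the S8 domain of a
characterized tomato subtilase) remain pluggable anywhere an anchor is
accepted.

The S8 anchor carries four designated "catalytic" positions holding the
Asp/His/Asn/Ser machinery of subtilisin-like proteases, and one designated
position playing the role of His331 in tobacco-phytaspase numbering (the S1
substrate-pocket residue read out by the phytaspase subtype classifier).
"""

from __future__ import annotations

# 150-residue synthetic S8 (peptidase domain) anchor.
S8_ANCHOR: str = (
    "RPEQDIRDVPKWISDQRSQLAHLTACPAQLNSGYWNLERHCFTKMFDAVT"
    "MRWDLRSQKYWPTRHPAVDPWPMDNHIDKAQRDCVNISCWLVNHFQWGIE"
    "HELHEAYVEFFRDDYPRMVSCYGMVWCSMSGSYHQCHKMDCGQCGSFSSN"
)

# 60-residue synthetic I9 (prodomain) anchor.
I9_ANCHOR: str = (
    "IESRMHEVPMETPGNSYECDTRKWMNKRGRIIPPNLMKTGWFRFHMCGQHLMEWARVVAW"
)

#: 0-based offsets of the four catalytic residues within S8_ANCHOR,
#: in N→C order (Asp, His, Asn, Ser).
CATALYTIC_OFFSETS: tuple[int, int, int, int] = (7, 39, 74, 129)

#: The catalytic residues at those offsets.
CATALYTIC_RESIDUES: str = "DHNS"

#: 0-based offset within S8_ANCHOR of the position playing the role of
#: residue 331 (tobacco-phytaspase numbering): the S1-pocket residue whose
#: identity (His/Lys/Gly) subtypes Asp-P1 candidates.
RES331_ANCHOR_OFFSET: int = 65

# Layout constants used by the synthetic SBT generator, all relative to the
# junction index j (0-based index of the first mature residue):
#   I9 anchor occupies [j - 70, j - 10)
#   the 12-mer junction window occupies [j - 6, j + 6)
#   S8 anchor occupies [j + 30, j + 180)
#   the residue-331 analog sits at j + 30 + RES331_ANCHOR_OFFSET = j + 95
I9_END_GAP: int = 10      # residues between I9 anchor end and the junction
S8_START_GAP: int = 30    # residues between the junction and S8 anchor start

assert len(S8_ANCHOR) == 150 and len(I9_ANCHOR) == 60
assert all(S8_ANCHOR[o] == r for o, r in zip(CATALYTIC_OFFSETS, CATALYTIC_RESIDUES))


def res331_offset_from_junction() -> int:
    """Offset of the residue-331 analog downstream of the junction."""
    return S8_START_GAP + RES331_ANCHOR_OFFSET
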