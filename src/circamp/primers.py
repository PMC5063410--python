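"""Primer, adapter-tag and read-layout constants for the targeted assays.

The sequences are the published primer set of the ASXL1 isoform study:
channel-specific amplicon primers for the bulk libraries (grep-style exact
matching assigns each read pair to the linear, circular or plasmid-control
reaction), and the single-cell RT-primer architecture whose read 2 carries
``<Clontech IIA><Nextera R2><4-nt filler><8-nt UMI><channel RT primer>``.
The filler (TCGA for the linear channel, AGCT for the circular one) and the
RT primer jointly identify the channel; the UMI sits immediately upstream
of the RT primer and is parsed by anchoring on that primer.
"""

from __future__ import annotations

from dataclasses import dataclass

# -- bulk amplicon sequencing -------------------------------------------------
# common tags added to every forward / reverse amplicon primer
FORWARD_COMMON_TAG = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
REVERSE_COMMON_TAG = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

LONG_F = "TGCTCCAATGACACCAAAAC"
LONG_R = "AGACCCACAGCTCTCCACAT"
SHORT_F = "GGGAGAAGGATGAAGGACAA"
SHORT_R = "CCCAAGCTTACAGCAGGTTC"
CIRCLE_F = "TCAATGCTATGCTACATTCCAATTC"
CIRCLE_R = "ATTGAGGCATGCGAGAGG"
PLASMID_E2_F = "CCAGCGGTACCTCATAGCAT"
PLASMID_E2_R = "TGAAACCCTCATGTTAAGCAA"
PLASMID_E3_F = "TGGATTGTATAACCCTCATCCA"
PLASMID_E3_R = "AAATTCATGGCCCCTATTCC"

LINEAR = "linear"
CIRCULAR = "circular"
PLASMID_CONTROL = "plasmid-control"
UNASSIGNED = "unassigned"

#: channel -> primers whose exact occurrence in either mate assigns the pair
BULK_PRIMER_SET: dict[str, tuple[str, ...]] = {
    LINEAR: (SHORT_F, SHORT_R),
    CIRCULAR: (CIRCLE_F, CIRCLE_R),
    PLASMID_CONTROL: (PLASMID_E2_F, PLASMID_E2_R, PLASMID_E3_F, PLASMID_E3_R),
}

# -- single-cell UMI-tagged libraries ----------------------------------------
CLONTECH_IIA = "AAGCAGTGGTATCAACGCAGA"
NEXTERA_READ2 = "GTGTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

SC_LINEAR_F = "ATGAAGGACAAACAGAAGAAGAAGA"
SC_CIRCLE_F = CIRCLE_F

#: channel-specific forward primer found in read 1
SC_FORWARD_PRIMERS: dict[str, str] = {LINEAR: SC_LINEAR_F, CIRCULAR: SC_CIRCLE_F}
#: channel-specific RT primer found in read 2, downstream of the UMI
RT_PRIMERS: dict[str, str] = {LINEAR: SHORT_R, CIRCULAR: CIRCLE_R}
#: 4-nt filler preceding the UMI in read 2
FILLERS: dict[str, str] = {LINEAR: "TCGA", CIRCULAR: "AGCT"}


@dataclass(frozen=True)
class Read2Layout:
    """Layout of a single-cell read 2 for one channel."""

    channel: str
    filler: str
    rt_primer: str
    umi_length: int = 8
    clontech: str = CLONTECH_IIA
    nextera_read2: str = NEXTERA_READ2

    @property
    def prefix(self) -> str:
        """Fixed sequence upstream of the UMI."""
        return self.clontech + self.nextera_read2 + self.filler


def read2_layout(channel: str, umi_length: int = 8) -> Read2Layout:
    if channel not in RT_PRIMERS:
        raise ValueError(f"unknown single-cell channel {channel!r}")
    return Read2Layout(
        channel=channel,
        filler=FILLERS[channel],
        rt_primer=RT_PRIMERS[channel],
        umi_length=umi_length,
    )
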