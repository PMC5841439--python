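"""Packaged reference fixture: 24 conserved-event records for the mouse
Tnip1-knockout vs human psoriasis comparison (gene pair, delta PSI in each
species, isoform-conservation label).

The PSI-consistency column is recomputed by the caller, not stored, so the
fixture exercises the consistency rule rather than restating its output.
"""

from __future__ import annotations

from .conservation import ConservedEventCall

# (gene_human, gene_mouse, dpsi_human, dpsi_mouse, isoform_conservation)
_ROWS: list[tuple[str, str, float, float, str]] = [
    ("ABI1", "Abi1", -0.133, -0.095, "both"),
    ("ARHGAP12", "Arhgap12", -0.069, -0.309, "both"),
    ("ATP5C1", "Atp5c1", 0.104, 0.259, "both"),
    ("CTTN", "Cttn", -0.054, -0.159, "both"),
    ("DNM1L", "Dnm1l", -0.096, -0.221, "both"),
    ("EXOC1", "Exoc1", 0.186, 0.198, "both"),
    ("FBLN2", "Fbln2", -0.172, -0.173, "both"),
    ("FNBP1", "Fnbp1", -0.137, -0.269, "both"),
    ("GOLGA2", "Golga2", -0.099, -0.144, "both"),
    ("GOLGA4", "Golga4", 0.058, 0.086, "both"),
    ("MYH11", "Myh11", -0.064, -0.225, "both"),
    ("MYL6", "Myl6", -0.101, -0.294, "both"),
    ("MYO1B", "Myo1b", -0.109, -0.206, "both"),
    ("PAM", "Pam", -0.096, -0.327, "both"),
    ("SEC31A", "Sec31a", -0.105, -0.115, "both"),
    ("SLK", "Slk", 0.107, 0.217, "both"),
    ("SPAG9", "Spag9", -0.100, -0.226, "both"),
    ("ZMYND11", "Zmynd11", 0.061, 0.365, "both"),
    ("AXL", "Axl", -0.060, 0.091, "both"),
    ("DMKN", "Dmkn", -0.180, -0.078, "cross_matched"),
    ("MLX", "Mlx", 0.089, -0.132, "both"),
    ("MPRIP", "Mprip", -0.127, 0.187, "both"),
    ("NDRG2", "Ndrg2", 0.126, -0.159, "both"),
    ("POSTN", "Postn", -0.072, -0.195, "cross_matched"),
]


def table1_fixture() -> list[ConservedEventCall]:
    """The 24 conserved-event input records; PSI consistency is computed by
    :class:`ConservedEventCall` on construction."""
    return [
        ConservedEventCall(
            gene_a=human, gene_b=mouse, dpsi_a=dh, dpsi_b=dm, label=label
        )
        for human, mouse, dh, dm, label in _ROWS
    ]
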