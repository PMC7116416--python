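"""Reference protocols and published counts used as fixed inputs.

These are printed acquisition parameters, stored as data: the neonatal
dHCP multi-shell protocol that this optimisation framework was used to
design, and the pilot acquisition grid on which the signal basis was
measured.
"""

from .io import ShellScheme

__all__ = [
    "DHCP_NEONATAL_PROTOCOL",
    "PILOT_BVALUES",
    "PILOT_SCHEME",
    "DHCP_FRACTION_PERCENTAGES",
]

#: Final dHCP neonatal protocol: 20 b=0 volumes plus shells at
#: b = 400/1000/2600 s/mm² with 64/88/128 directions (300 volumes total).
DHCP_NEONATAL_PROTOCOL = ShellScheme(
    bvalues=(0.0, 400.0, 1000.0, 2600.0),
    counts=(20, 64, 88, 128),
)

#: Published per-shell volume proportions of the 3-shell scheme, percent.
DHCP_FRACTION_PERCENTAGES = (6, 19, 28, 47)

#: Pilot acquisition b-value grid (s/mm²): 5 b=0 volumes and 50
#: electrostatically uniform directions per nonzero shell.
PILOT_BVALUES = (0.0, 500.0, 1000.0, 2000.0, 3000.0, 4000.0)
PILOT_SCHEME = ShellScheme(bvalues=PILOT_BVALUES, counts=(5, 50, 50, 50, 50, 50))
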