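"""Physical constants shared across the package."""

#: Proton gyromagnetic ratio over 2π, in Hz/T.
GAMMA_HZ_PER_T = 42.577478e6
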