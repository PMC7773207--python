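"""Shared test vocabulary: the legal per-tooth lifecycle transitions."""

LEGAL_TRANSITIONS = {
    ("successor", None, "crypt"),
    ("successor", "crypt", "germ"),
    ("successor", "germ", "erupting"),
    ("successor", "erupting", "functional"),
    ("tooth", None, "functional"),
    ("tooth", "functional", "resorbing"),
    ("tooth", "resorbing", "shed_with_remnant_root"),
    ("tooth", "shed_with_remnant_root", None),
}
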