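"""Packaged rule-set and declarative-network fixtures (plain-text DSL)."""

from importlib import resources


def load_text(name: str) -> str:
    return resources.files(__package__).joinpath(name).read_text()
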