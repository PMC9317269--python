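"""Bundled scenario fixtures for the Honghe Hani terraces study area."""

from importlib import resources
from pathlib import Path


def fixture_path(name: str) -> Path:
    """Absolute path of a bundled data file (e.g. ``hani_2020.yaml``)."""
    return Path(resources.files(__package__) / name)


HANI_2020 = "hani_2020.yaml"
MONOCULTURE_2020 = "monoculture_2020.yaml"
HANI_2020_REFERENCE = "hani_2020_reference.yaml"
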