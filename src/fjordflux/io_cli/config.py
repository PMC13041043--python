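"""YAML configuration loading (envelopes, station roles, gene panel) and a
minimal run log."""

from __future__ import annotations

import hashlib
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ..genecov import GenePanel, default_panel
from ..mixing import StationRoles
from ..watermass import EnvelopeTable, default_envelope_table

__all__ = [
    "load_envelopes",
    "load_roles",
    "load_panel",
    "RunLog",
]


def load_envelopes(path=None) -> EnvelopeTable:
    if path is None:
        return default_envelope_table()
    return EnvelopeTable.from_yaml(path)


def load_roles(path) -> StationRoles:
    with open(path, encoding="utf-8") as fh:
        return StationRoles.from_dict(yaml.safe_load(fh))


def load_panel(path=None) -> GenePanel:
    if path is None:
        return default_panel()
    return GenePanel.from_yaml(path)


@dataclass
class RunLog:
    """Collects audit messages and counters for one pipeline run."""

    command: str
    messages: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    def note(self, message: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.messages.append(f"{stamp} {message}")

    def count(self, key: str, value: int) -> None:
        self.counts[key] = int(value)
        self.note(f"{key} = {value}")

    def config_hash(self, path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]
        self.note(f"config {path} sha256:{digest}")

    def write(self, out_path=None) -> None:
        lines = [f"# fjordflux {self.command}"] + self.messages
        text = "\n".join(lines) + "\n"
        if out_path is None:
            sys.stderr.write(text)
        else:
            Path(out_path).write_text(text, encoding="utf-8")
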