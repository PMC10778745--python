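"""Shared fixtures: synthetic datasets and pipeline runs at two scales."""

from __future__ import annotations

import json

import pytest

from mirnaome import orchestration
from mirnaome.synthetic_data import TruthManifest


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_fixture")
    orchestration.make_fixture(out, preset="tiny", seed=42)
    return out


@pytest.fixture(scope="session")
def tiny_manifest(tiny_fixture) -> TruthManifest:
    return TruthManifest.from_json((tiny_fixture / "manifest.json").read_text())


@pytest.fixture(scope="session")
def tiny_run(tiny_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_out")
    inputs = orchestration.fixture_inputs(tiny_fixture)
    return orchestration.run_pipeline(inputs, out), out


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The full study-scale dataset: 30 planted genes, 7 decoys, 20 libraries."""
    out = tmp_path_factory.mktemp("default_fixture")
    orchestration.make_fixture(out, preset="default", seed=42)
    return out


@pytest.fixture(scope="session")
def default_manifest(default_fixture) -> TruthManifest:
    return TruthManifest.from_json((default_fixture / "manifest.json").read_text())


@pytest.fixture(scope="session")
def default_run(default_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("default_out")
    inputs = orchestration.fixture_inputs(default_fixture)
    return orchestration.run_pipeline(inputs, out), out
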