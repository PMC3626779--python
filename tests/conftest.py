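import pytest

from icmolar.synthetic_data import tables_to_records


@pytest.fixture
def write_csv(tmp_path):
    """Write a CSV from a header line and rows; returns the path."""

    def _write(name, header, rows):
        path = tmp_path / name
        lines = [header] + [",".join(str(v) for v in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def frames_to_records(measurements, metadata):
    """Run the simulator's in-memory tables through the data pipeline,
    returning genus records (the morphospace input)."""
    return tables_to_records(measurements, metadata)
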