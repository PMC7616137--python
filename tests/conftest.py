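import datetime as dt
from pathlib import Path

import numpy as np
import pytest

from trekit.backend import ISO_DIALECT, write_database
from trekit.fixtures import (
    demo_definition,
    diamond_project_yaml,
    three_patient_database,
)
from trekit.query import serialize

DATA_DIR = Path(__file__).parent / "data"

# scripts for the diamond project's exec-script actions
DIAMOND_SCRIPTS = {
    "counts.py": (
        "import csv\n"
        "rows = list(csv.reader(open('output/dataset.csv')))\n"
        "open('output/counts.csv', 'w').write('group,n\\nall,%d\\n' % (len(rows) - 1))\n"
    ),
    "values.py": "open('output/values.csv', 'w').write('metric,value\\nmean_age,32\\n')\n",
    "join.py": (
        "a = open('output/counts.csv').read()\n"
        "b = open('output/values.csv').read()\n"
        "open('output/joined.csv', 'w').write(a + b)\n"
    ),
    "report.py": "open('output/report.csv', 'w').write(open('output/joined.csv').read())\n",
    "note.py": "open('output/note.csv', 'w').write('note,ok\\n')\n",
}


@pytest.fixture
def db3():
    return three_patient_database()


@pytest.fixture
def demo_dd():
    return demo_definition()


@pytest.fixture
def golden_csv() -> str:
    return (DATA_DIR / "demo_extraction_golden.csv").read_text()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def diamond_workspace(tmp_path, db3, demo_dd):
    """Workspace directory with the diamond project, its inputs and scripts."""
    ws = tmp_path / "ws"
    (ws / "analysis").mkdir(parents=True)
    (ws / "project.yaml").write_text(diamond_project_yaml())
    (ws / "analysis" / "definition.json").write_text(serialize(demo_dd))
    write_database(db3, ws / "database", ISO_DIALECT)
    for name, body in DIAMOND_SCRIPTS.items():
        (ws / "analysis" / name).write_text(body)
    return ws
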