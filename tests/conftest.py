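import numpy as np
import pandas as pd
import pytest

import faerspv as f


@pytest.fixture(scope="session")
def small_dataset():
    """One synthetic quarter with a planted target-drug signal, shared
    read-only across tests."""
    cfg = f.SimulationConfig(
        n_reports=1500,
        seed=42,
        planted_signals=(("ORKAMBI", "Depression", 5.0),),
    )
    tables, truth = f.generate_tables(cfg)
    return cfg, tables, truth


@pytest.fixture(scope="session")
def assembled(small_dataset):
    cfg, tables, truth = small_dataset
    retained = f.deduplicate(tables.demo)
    retained = f.remove_deleted_cases(retained, tables.deleted_caseids, tables.demo)
    target_ids = f.select_drug_reports(tables.drug, ("ORKAMBI",)) & retained
    cases = f.assemble_cases(tables, target_ids, cfg.pt_to_soc, ("ORKAMBI",))
    records = f.pt_record_table(tables, retained, cfg.pt_to_soc)
    return cfg, truth, retained, target_ids, cases, records


def write_demo_file(path, rows, header="primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$wt$wt_cod$occp_cod$reporter_country"):
    lines = [header] + rows
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture()
def tiny_quarter(tmp_path):
    """A hand-written three-report quarter exercising every table."""
    (tmp_path / "DEMO15Q3.txt").write_text(
        "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$wt$wt_cod$occp_cod$reporter_country\n"
        "1001$100$20160101$20150913$24$MON$F$110$LBS$CN$US\n"
        "1002$101$20170101$20161201$30$YR$M$$$MD$GB\n"
        "1003$102$20170301$$12$YR$F$40$KG$PH$US\n",
        encoding="utf-8",
    )
    (tmp_path / "DRUG15Q3.txt").write_text(
        "primaryid$drug_seq$role_cod$drugname$dose_amt$dose_freq\n"
        "1001$1$PS$Orkambi$200/125$BID\n"
        "1001$2$C$PULMOZYME$$\n"
        "1002$1$PS$ORKAMBI$400/250$QD\n"
        "1003$1$PS$KALYDECO$$BID\n",
        encoding="utf-8",
    )
    (tmp_path / "REAC15Q3.txt").write_text(
        "primaryid$pt\n1001$Cough\n1001$Dyspnoea\n1002$Depression\n1003$Cough\n",
        encoding="utf-8",
    )
    (tmp_path / "INDI15Q3.txt").write_text(
        "primaryid$indi_drug_seq$indi_pt\n1001$1$Cystic fibrosis\n1002$1$Cystic fibrosis\n",
        encoding="utf-8",
    )
    (tmp_path / "THER15Q3.txt").write_text(
        "primaryid$dsg_drug_seq$start_dt$end_dt\n1001$1$20150801$\n1002$1$201605$\n",
        encoding="utf-8",
    )
    (tmp_path / "OUTC15Q3.txt").write_text(
        "primaryid$outc_cod\n1001$HO\n1002$DE\n",
        encoding="utf-8",
    )
    return tmp_path


PT_SOC = {
    "Cough": "Respiratory, thoracic and mediastinal disorders",
    "Dyspnoea": "Respiratory, thoracic and mediastinal disorders",
    "Depression": "Psychiatric disorders",
}
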