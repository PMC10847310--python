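"""Reference characteristic distribution for HER2-inhibitor hemorrhagic cases.

A published worked example: N = 1,274 spontaneous reports with a hemorrhagic
event, tabulated by regimen, age band, sex, outcome code, system organ class
and preferred term, with the percents as printed (two significant figures).
Each case carries exactly one hemorrhagic PT, so the PT counts sum to N and
the SOC counts are the sums of their member PTs.
"""

N_CASES = 1274

REGIMEN = [
    ("Combination therapy", 352, "28%"),
    ("Monotherapy", 922, "72%"),
]

AGE = [
    ("<18", 7, "0.5%"),
    ("≥75", 94, "7.4%"),
    ("18–44", 108, "8.5%"),
    ("45–64", 544, "43%"),
    ("65–74", 198, "16%"),
    ("Unknown", 323, "25%"),
]

SEX = [
    ("F", 1051, "82%"),
    ("M", 99, "7.8%"),
    ("Unknown", 124, "9.7%"),
]

OUTCOME = [
    ("CA", 1, "<0.1%"),
    ("DE", 294, "23%"),
    ("DS", 18, "1.4%"),
    ("HO", 477, "37%"),
    ("LT", 23, "1.8%"),
    ("OT", 457, "36%"),
    ("Unknown", 4, "0.3%"),
]

SOC = [
    ("Eye disorders", 83, "6.5%"),
    ("Gastrointestinal disorders", 661, "52%"),
    ("Hepatobiliary disorders", 4, "0.3%"),
    ("Neoplasms benign, malignant and unspecified", 59, "4.6%"),
    ("Nervous system disorders", 175, "14%"),
    ("Renal and urinary disorders", 39, "3.1%"),
    ("Reproductive system and breast disorders", 8, "0.6%"),
    ("Respiratory, thoracic and mediastinal disorders", 37, "2.9%"),
    ("Vascular disorders", 208, "16%"),
]

# (preferred term, SOC, count, printed percent)
PT = [
    ("Anal haemorrhage", "Gastrointestinal disorders", 7, "0.5%"),
    ("Arterial haemorrhage", "Vascular disorders", 1, "<0.1%"),
    ("Bronchial haemorrhage", "Respiratory, thoracic and mediastinal disorders", 3, "0.2%"),
    ("Central nervous system haemorrhage", "Nervous system disorders", 3, "0.2%"),
    ("Cerebral haemorrhage", "Nervous system disorders", 107, "8.4%"),
    ("Cerebral microhaemorrhage", "Nervous system disorders", 1, "<0.1%"),
    ("Conjunctival haemorrhage", "Eye disorders", 9, "0.7%"),
    ("Cystitis haemorrhagic", "Renal and urinary disorders", 27, "2.1%"),
    ("Diarrhoea haemorrhagic", "Gastrointestinal disorders", 46, "3.6%"),
    ("Duodenal ulcer haemorrhage", "Gastrointestinal disorders", 8, "0.6%"),
    ("Enterocolitis haemorrhagic", "Gastrointestinal disorders", 7, "0.5%"),
    ("Eye haemorrhage", "Eye disorders", 44, "3.5%"),
    ("Gastric haemorrhage", "Gastrointestinal disorders", 43, "3.4%"),
    ("Gastritis haemorrhagic", "Gastrointestinal disorders", 5, "0.4%"),
    ("Gastroduodenal haemorrhage", "Gastrointestinal disorders", 2, "0.2%"),
    ("Gastrointestinal haemorrhage", "Gastrointestinal disorders", 214, "17%"),
    ("Haemorrhage", "Vascular disorders", 191, "15%"),
    ("Haemorrhage intracranial", "Nervous system disorders", 26, "2.0%"),
    ("Haemorrhage urinary tract", "Renal and urinary disorders", 4, "0.3%"),
    ("Haemorrhagic ascites", "Gastrointestinal disorders", 2, "0.2%"),
    ("Haemorrhagic stroke", "Nervous system disorders", 12, "0.9%"),
    ("Haemorrhoidal haemorrhage", "Gastrointestinal disorders", 21, "1.6%"),
    ("Haemorrhoids", "Gastrointestinal disorders", 41, "3.2%"),
    ("Hepatic haemorrhage", "Hepatobiliary disorders", 4, "0.3%"),
    ("Internal haemorrhage", "Vascular disorders", 7, "0.5%"),
    ("Intestinal haemorrhage", "Gastrointestinal disorders", 22, "1.7%"),
    ("Intra-abdominal haemorrhage", "Gastrointestinal disorders", 1, "<0.1%"),
    ("Intracranial tumour haemorrhage", "Neoplasms benign, malignant and unspecified", 10, "0.8%"),
    ("Intraventricular haemorrhage", "Nervous system disorders", 6, "0.5%"),
    ("Laryngeal haemorrhage", "Respiratory, thoracic and mediastinal disorders", 1, "<0.1%"),
    ("Lip haemorrhage", "Gastrointestinal disorders", 3, "0.2%"),
    ("Mouth haemorrhage", "Gastrointestinal disorders", 35, "2.7%"),
    ("Naevus haemorrhage", "Neoplasms benign, malignant and unspecified", 6, "0.5%"),
    ("Oesophageal haemorrhage", "Gastrointestinal disorders", 5, "0.4%"),
    ("Oesophageal varices haemorrhage", "Gastrointestinal disorders", 9, "0.7%"),
    ("Oesophagitis haemorrhagic", "Gastrointestinal disorders", 1, "<0.1%"),
    ("Optic disc haemorrhage", "Eye disorders", 1, "<0.1%"),
    ("Pulmonary haemorrhage", "Respiratory, thoracic and mediastinal disorders", 27, "2.1%"),
    ("Rectal haemorrhage", "Gastrointestinal disorders", 186, "15%"),
    ("Renal haemorrhage", "Renal and urinary disorders", 1, "<0.1%"),
    ("Respiratory tract haemorrhage", "Respiratory, thoracic and mediastinal disorders", 5, "0.4%"),
    ("Retinal haemorrhage", "Eye disorders", 29, "2.3%"),
    ("Retroperitoneal haemorrhage", "Gastrointestinal disorders", 3, "0.2%"),
    ("Shock haemorrhagic", "Vascular disorders", 7, "0.5%"),
    ("Subarachnoid haemorrhage", "Nervous system disorders", 19, "1.5%"),
    ("Thalamus haemorrhage", "Nervous system disorders", 1, "<0.1%"),
    ("Thoracic haemorrhage", "Respiratory, thoracic and mediastinal disorders", 1, "<0.1%"),
    ("Tumour haemorrhage", "Neoplasms benign, malignant and unspecified", 43, "3.4%"),
    ("Ureteric haemorrhage", "Renal and urinary disorders", 1, "<0.1%"),
    ("Urethral haemorrhage", "Renal and urinary disorders", 1, "<0.1%"),
    ("Urinary bladder haemorrhage", "Renal and urinary disorders", 5, "0.4%"),
    ("Uterine haemorrhage", "Reproductive system and breast disorders", 8, "0.6%"),
    ("Venous haemorrhage", "Vascular disorders", 2, "0.2%"),
]
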