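"""Bundled drug-like structures used by the synthetic data generator.

Each entry is (preferred name, canonical SMILES) for a well-known,
public-domain small molecule.  The generator draws compound structures
from this list so that chemical descriptors are computable and span a
realistic range of drug-like property space.
"""

from __future__ import annotations

MELATONIN_SMILES = "CC(=O)NCCc1c[nH]c2ccc(OC)cc12"
TASIMELTEON_SMILES = "CCC(=O)NC[C@@H]1C[C@H]1c1cccc2OCCc12"

#: (pref_name, smiles) pairs; names are the common INN/USAN.
DRUG_STRUCTURES: list[tuple[str, str]] = [
    ("Melatonin", MELATONIN_SMILES),
    ("Tasimelteon", TASIMELTEON_SMILES),
    ("Ramelteon", "CCC(=O)NCC[C@@H]1CCc2c1cc1CCOc1c2"),
    ("Agomelatine", "CC(=O)NCCc1ccc(OC)c2ccccc12"),
    ("Aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("Paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("Ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("Naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1"),
    ("Diclofenac", "OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl"),
    ("Indomethacin", "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1"),
    ("Celecoxib", "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1"),
    ("Caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("Theophylline", "Cn1c(=O)c2[nH]cnc2n(C)c1=O"),
    ("Atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("Metoprolol", "COCCc1ccc(OCC(O)CNC(C)C)cc1"),
    ("Propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("Carvedilol", "COc1ccccc1OCCNCC(O)COc1cccc2[nH]c3ccccc3c12"),
    ("Labetalol", "CC(CCc1ccccc1)NCC(O)c1ccc(O)c(C(N)=O)c1"),
    ("Amlodipine", "CCOC(=O)C1=C(COCCN)NC(C)=C(C(=O)OC)C1c1ccccc1Cl"),
    ("Nifedipine", "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]"),
    ("Verapamil", "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC"),
    ("Diltiazem", "COc1ccc([C@@H]2Sc3ccccc3N(CCN(C)C)C(=O)[C@@H]2OC(C)=O)cc1"),
    ("Lisinopril", "NCCCC[C@H](N[C@@H](CCc1ccccc1)C(=O)O)C(=O)N1CCC[C@H]1C(=O)O"),
    ("Enalapril", "CCOC(=O)[C@H](CCc1ccccc1)N[C@@H](C)C(=O)N1CCC[C@H]1C(=O)O"),
    ("Captopril", "C[C@@H](CS)C(=O)N1CCC[C@H]1C(=O)O"),
    ("Losartan", "CCCCc1nc(Cl)c(CO)n1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1"),
    ("Valsartan", "CCCCC(=O)N(Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1)[C@@H](C(C)C)C(=O)O"),
    ("Irbesartan", "CCCCC1=NC2(CCCC2)C(=O)N1Cc1ccc(-c2ccccc2-c2nnn[nH]2)cc1"),
    ("Hydrochlorothiazide", "NS(=O)(=O)c1cc2c(cc1Cl)NCNS2(=O)=O"),
    ("Furosemide", "NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl"),
    ("Spironolactone", "CC(=O)S[C@@H]1CC2=CC(=O)CC[C@]2(C)[C@H]2CC[C@]3(C)[C@@H](CC[C@]34CCC(=O)O4)[C@@H]12"),
    ("Digoxin", "C[C@H]1O[C@H](O[C@@H]2[C@H](O)C[C@@H](O[C@@H]3[C@H](O)C[C@@H](O[C@H]4CC[C@]5(C)[C@H](CC[C@@H]6[C@@H]5CC[C@]5(C)[C@H](C7=CC(=O)OC7)CC[C@@]65O)C4)O[C@@H]3C)O[C@@H]2C)C[C@@H](O)[C@@H]1O"),
    ("Warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("Clopidogrel", "COC(=O)[C@H](c1ccccc1Cl)N1CCc2sccc2C1"),
    ("Atorvastatin", "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1CC[C@@H](O)C[C@@H](O)CC(=O)O"),
    ("Simvastatin", "CC[C@](C)(C(=O)O[C@H]1C[C@@H](C)C=C2C=C[C@H](C)[C@H](CC[C@@H]3C[C@@H](O)CC(=O)O3)[C@@H]12)C"),
    ("Pravastatin", "CC[C@H](C)C(=O)O[C@H]1C[C@@H](O)C=C2C=C[C@H](C)[C@H](CC[C@@H](O)C[C@@H](O)CC(=O)O)[C@@H]12"),
    ("Gemfibrozil", "Cc1ccc(C)c(OCCCC(C)(C)C(=O)O)c1"),
    ("Metformin", "CN(C)C(=N)NC(N)=N"),
    ("Glipizide", "Cc1cnc(C(=O)NCCc2ccc(S(=O)(=O)NC(=O)NC3CCCCC3)cc2)cn1"),
    ("Gliclazide", "Cc1ccc(S(=O)(=O)NC(=O)NN2CC3CCCC3C2)cc1"),
    ("Pioglitazone", "CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1"),
    ("Sitagliptin", "N[C@@H](CC(=O)N1CCn2c(nnc2C(F)(F)F)C1)Cc1cc(F)c(F)cc1F"),
    ("Omeprazole", "COc1ccc2[nH]c(S(=O)Cc3ncc(C)c(OC)c3C)nc2c1"),
    ("Ranitidine", "CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1"),
    ("Cimetidine", "CC1=C(CSCCNC(=NC)NC#N)N=CN1"),
    ("Loperamide", "CN(C)C(=O)C(CCN1CCC(O)(c2ccc(Cl)cc2)CC1)(c1ccccc1)c1ccccc1"),
    ("Ondansetron", "Cc1nccn1CC1CCc2c(C1=O)c1ccccc1n2C"),
    ("Metoclopramide", "CCN(CC)CCNC(=O)c1cc(Cl)c(N)cc1OC"),
    ("Prazosin", "COc1cc2nc(N3CCN(C(=O)c4ccco4)CC3)nc(N)c2cc1OC"),
    ("Doxazosin", "COc1cc2nc(N3CCN(C(=O)C4COc5ccccc5O4)CC3)nc(N)c2cc1OC"),
    ("Tamsulosin", "CCOc1ccccc1OCCN[C@H](C)Cc1ccc(OC)c(S(N)(=O)=O)c1"),
    ("Sildenafil", "CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCN(C)CC4)ccc3OCC)nc12"),
    ("Fluoxetine", "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1"),
    ("Sertraline", "CN[C@H]1CC[C@@H](c2ccc(Cl)c(Cl)c2)c2ccccc21"),
    ("Paroxetine", "Fc1ccc([C@@H]2CCNC[C@H]2COc2ccc3OCOc3c2)cc1"),
    ("Citalopram", "CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21"),
    ("Venlafaxine", "COc1ccc(C(CN(C)C)C2(O)CCCCC2)cc1"),
    ("Duloxetine", "CNCC[C@H](Oc1ccc2ccccc2c1)c1cccs1"),
    ("Amitriptyline", "CN(C)CCC=C1c2ccccc2CCc2ccccc21"),
    ("Imipramine", "CN(C)CCCN1c2ccccc2CCc2ccccc21"),
    ("Mirtazapine", "CN1CCN2c3ccccc3Cc3cccnc3C2C1"),
    ("Trazodone", "O=c1n(CCCN2CCN(c3cccc(Cl)c3)CC2)nc2ccccn12"),
    ("Buspirone", "O=C1CC2(CCCC2)CC(=O)N1CCCCN1CCN(c2ncccn2)CC1"),
    ("Diazepam", "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O"),
    ("Lorazepam", "OC1N=C(c2ccccc2Cl)c2cc(Cl)ccc2NC1=O"),
    ("Alprazolam", "Cc1nnc2CN=C(c3ccccc3)c3cc(Cl)ccc3-n12"),
    ("Zolpidem", "CN(C)C(=O)Cc1c(-c2ccc(C)cc2)nc2ccc(C)cn12"),
    ("Haloperidol", "OC1(c2ccc(Cl)cc2)CCN(CCCC(=O)c2ccc(F)cc2)CC1"),
    ("Risperidone", "Cc1nc2n(c1CCN1CCC(c3noc4cc(F)ccc34)CC1)CCCC2=O"),
    ("Olanzapine", "Cc1cc2c(s1)Nc1ccccc1N=C2N1CCN(C)CC1"),
    ("Quetiapine", "OCCOCCN1CCN(C2=Nc3ccccc3Sc3ccccc32)CC1"),
    ("Clozapine", "CN1CCN(C2=Nc3cc(Cl)ccc3Nc3ccccc32)CC1"),
    ("Aripiprazole", "O=C1CCc2ccc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)cc2N1"),
    ("Carbamazepine", "NC(=O)N1c2ccccc2C=Cc2ccccc21"),
    ("Lamotrigine", "Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1"),
    ("Gabapentin", "NCC1(CC(=O)O)CCCCC1"),
    ("Pregabalin", "CC(C)C[C@H](CN)CC(=O)O"),
    ("Valproate", "CCCC(CCC)C(=O)O"),
    ("Phenytoin", "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1"),
    ("Levetiracetam", "CC[C@H](C(N)=O)N1CCCC1=O"),
    ("Topiramate", "CC1(C)O[C@@H]2CO[C@@]3(COS(N)(=O)=O)OC(C)(C)O[C@H]3[C@@H]2O1"),
    ("Sumatriptan", "CNS(=O)(=O)Cc1ccc2[nH]cc(CCN(C)C)c2c1"),
    ("Rizatriptan", "CN(C)CCc1c[nH]c2ccc(Cn3cncn3)cc12"),
    ("Ergotamine", "C[C@@]1(NC(=O)[C@H]2C=C3c4cccc5[nH]cc(c45)C[C@H]3N(C)C2)O[C@]2(O)[C@@H]3CCCN3C(=O)[C@H](Cc3ccccc3)N2C1=O"),
    ("Morphine", "CN1CC[C@]23c4c5ccc(O)c4O[C@H]2[C@@H](O)C=C[C@H]3[C@H]1C5"),
    ("Codeine", "COc1ccc2C[C@@H]3[C@@H]4C=C[C@@H](O)[C@H]5Oc1c2[C@]45CCN3C"),
    ("Tramadol", "CN(C)C[C@H]1CCCC[C@]1(O)c1cccc(OC)c1"),
    ("Fentanyl", "CCC(=O)N(c1ccccc1)C1CCN(CCc2ccccc2)CC1"),
    ("Naloxone", "C=CCN1CC[C@]23c4c5ccc(O)c4O[C@H]2C(=O)CC[C@@]3(O)[C@H]1C5"),
    ("Methadone", "CCC(=O)C(CC(C)N(C)C)(c1ccccc1)c1ccccc1"),
    ("Lidocaine", "CCN(CC)CC(=O)Nc1c(C)cccc1C"),
    ("Procaine", "CCN(CC)CCOC(=O)c1ccc(N)cc1"),
    ("Bupivacaine", "CCCCN1CCCCC1C(=O)Nc1c(C)cccc1C"),
    ("Amiodarone", "CCCCc1oc2ccccc2c1C(=O)c1cc(I)c(OCCN(CC)CC)c(I)c1"),
    ("Flecainide", "O=C(NCC1CCCCN1)c1cc(OCC(F)(F)F)ccc1OCC(F)(F)F"),
    ("Sotalol", "CC(C)NCC(O)c1ccc(NS(C)(=O)=O)cc1"),
    ("Quinidine", "C=C[C@H]1CN2CC[C@H]1C[C@H]2[C@@H](O)c1ccnc2ccc(OC)cc12"),
    ("Dofetilide", "CN(CCOc1ccc(NS(C)(=O)=O)cc1)CCc1ccc(NS(C)(=O)=O)cc1"),
    ("Ivabradine", "COc1cc2c(cc1OC)C1CC1CN(CCCN(C)C[C@H]1Cc3cc(OC)c(OC)cc31)CC2"),
    ("Ranolazine", "Cc1ccccc1N(C(=O)CN1CCN(CC(O)COc2ccccc2OC)CC1)C"),
    ("Dobutamine", "CC(CCc1ccc(O)cc1)NCCc1ccc(O)c(O)c1"),
    ("Dopamine", "NCCc1ccc(O)c(O)c1"),
    ("Epinephrine", "CNC[C@H](O)c1ccc(O)c(O)c1"),
    ("Norepinephrine", "NC[C@H](O)c1ccc(O)c(O)c1"),
    ("Isoprenaline", "CC(C)NC[C@H](O)c1ccc(O)c(O)c1"),
    ("Salbutamol", "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1"),
    ("Salmeterol", "OCc1cc(C(O)CNCCCCCCOCCCCc2ccccc2)ccc1O"),
    ("Clonidine", "Clc1cccc(Cl)c1NC1=NCCN1"),
    ("Prednisone", "CC12CC(=O)C3C(CCC4=CC(=O)C=CC43C)C1CCC2(O)C(=O)CO"),
    ("Dexamethasone", "C[C@@H]1C[C@H]2[C@@H]3CCC4=CC(=O)C=C[C@]4(C)[C@@]3(F)[C@@H](O)C[C@]2(C)[C@@]1(O)C(=O)CO"),
    ("Hydrocortisone", "C[C@]12CC[C@H]3[C@@H](CCC4=CC(=O)CC[C@]43C)[C@@H]1CC[C@@]2(O)C(=O)CO"),
    ("Testosterone", "C[C@]12CC[C@H]3[C@@H](CCC4=CC(=O)CC[C@]43C)[C@@H]1CC[C@@H]2O"),
    ("Estradiol", "C[C@]12CC[C@H]3[C@@H](CCc4cc(O)ccc43)[C@@H]1CC[C@@H]2O"),
    ("Progesterone", "CC(=O)[C@H]1CC[C@H]2[C@@H]3CCC4=CC(=O)CC[C@]4(C)[C@H]3CC[C@]12C"),
    ("Tamoxifen", "CC/C(=C(\\c1ccccc1)c1ccc(OCCN(C)C)cc1)c1ccccc1"),
    ("Raloxifene", "Oc1ccc(cc1)C1=C(c2ccc(OCCN3CCCCC3)cc2)c2cc(O)ccc2S1"),
    ("Finasteride", "CC(C)(C)NC(=O)[C@H]1CC[C@H]2[C@@H]3CC[C@H]4NC(=O)C=C[C@]4(C)[C@H]3CC[C@]12C"),
    ("Levothyroxine", "N[C@@H](Cc1cc(I)c(Oc2cc(I)c(O)c(I)c2)c(I)c1)C(=O)O"),
    ("Amoxicillin", "CC1(C)S[C@@H]2[C@H](NC(=O)[C@H](N)c3ccc(O)cc3)C(=O)N2[C@H]1C(=O)O"),
    ("Ampicillin", "CC1(C)S[C@@H]2[C@H](NC(=O)[C@H](N)c3ccccc3)C(=O)N2[C@H]1C(=O)O"),
    ("Cephalexin", "CC1=C(C(=O)O)N2C(=O)[C@@H](NC(=O)[C@H](N)c3ccccc3)[C@H]2SC1"),
    ("Ciprofloxacin", "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O"),
    ("Levofloxacin", "C[C@H]1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(C(=O)O)cn1c23"),
    ("Trimethoprim", "COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC"),
    ("Sulfamethoxazole", "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1"),
    ("Metronidazole", "Cc1ncc([N+](=O)[O-])n1CCO"),
    ("Fluconazole", "OC(Cn1cncn1)(Cn1cncn1)c1ccc(F)cc1F"),
    ("Ketoconazole", "CC(=O)N1CCN(c2ccc(OC[C@H]3CO[C@](Cn4ccnc4)(c4ccc(Cl)cc4Cl)O3)cc2)CC1"),
    ("Aciclovir", "Nc1nc2c(c(=O)[nH]1)n(COCCO)cn2"),
    ("Oseltamivir", "CCOC(=O)C1=C[C@@H](OC(CC)CC)[C@H](NC(C)=O)[C@@H](N)C1"),
    ("Zidovudine", "Cc1cn([C@H]2C[C@H](N=[N+]=[N-])[C@@H](CO)O2)c(=O)[nH]c1=O"),
    ("Chloroquine", "CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12"),
    ("Mefloquine", "OC(c1cc(C(F)(F)F)nc2c(C(F)(F)F)cccc12)C1CCCCN1"),
    ("Albendazole", "CCCSc1ccc2[nH]c(NC(=O)OC)nc2c1"),
    ("Ivermectin", "CO[C@H]1C[C@H](O[C@H]2[C@H](C)O[C@H](O[C@H]3C[C@@H](C)C=C4C=C[C@H](C)[C@@H](C(C)CC)O[C@]45CC[C@H](C)C(=CC5)C3)C[C@@H]2OC)O[C@@H](C)[C@@H]1O"),
    ("Methotrexate", "CN(Cc1cnc2nc(N)nc(N)c2n1)c1ccc(C(=O)N[C@@H](CCC(=O)O)C(=O)O)cc1"),
    ("5-Fluorouracil", "O=c1[nH]cc(F)c(=O)[nH]1"),
    ("Imatinib", "Cc1ccc(NC(=O)c2ccc(CN3CCN(C)CC3)cc2)cc1Nc1nccc(-c2cccnc2)n1"),
    ("Gefitinib", "COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1OCCCN1CCOCC1"),
    ("Erlotinib", "COCCOc1cc2ncnc(Nc3cccc(C#C)c3)c2cc1OCCOC"),
    ("Sorafenib", "CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1"),
    ("Cisplatin-mim", "NCCN"),
    ("Allopurinol", "O=c1[nH]cnc2[nH]ncc12"),
    ("Colchicine", "COc1cc2CC[C@H](NC(C)=O)c3cc(=O)c(OC)ccc3-c2c(OC)c1OC"),
    ("Probenecid", "CCCN(CCC)S(=O)(=O)c1ccc(C(=O)O)cc1"),
    ("Montelukast", "CC(C)(O)c1ccccc1CC[C@H](SCC1(CC(=O)O)CC1)c1cccc(/C=C/c2ccc3ccc(Cl)cc3n2)c1"),
    ("Zafirlukast", "COc1cc(C(=O)NS(=O)(=O)c2ccccc2C)ccc1Cc1cn(C)c2ccc(NC(=O)OC3CCCC3)cc12"),
    ("Loratadine", "CCOC(=O)N1CCC(=C2c3ccc(Cl)cc3CCc3cccnc32)CC1"),
    ("Cetirizine", "OC(=O)COCCN1CCN(C(c2ccccc2)c2ccc(Cl)cc2)CC1"),
    ("Fexofenadine", "CC(C)(C(=O)O)c1ccc(C(O)CCCN2CCC(C(O)(c3ccccc3)c3ccccc3)CC2)cc1"),
    ("Diphenhydramine", "CN(C)CCOC(c1ccccc1)c1ccccc1"),
    ("Chlorpheniramine", "CN(C)CCC(c1ccc(Cl)cc1)c1ccccn1"),
    ("Promethazine", "CC(CN1c2ccccc2Sc2ccccc21)N(C)C"),
    ("Scopolamine", "CN1[C@H]2C[C@@H](OC(=O)[C@H](CO)c3ccccc3)C[C@@H]1[C@H]1O[C@@H]21"),
    ("Atropine", "CN1C2CCC1CC(OC(=O)C(CO)c1ccccc1)C2"),
    ("Pilocarpine", "CC[C@H]1[C@H](Cc2cncn2C)COC1=O"),
    ("Donepezil", "COc1cc2CC(CC3CCN(Cc4ccccc4)CC3)C(=O)c2cc1OC"),
    ("Rivastigmine", "CCN(C)C(=O)Oc1cccc([C@H](C)N(C)C)c1"),
    ("Memantine", "CC12CC3CC(C)(C1)CC(N)(C3)C2"),
    ("Levodopa", "N[C@@H](Cc1ccc(O)c(O)c1)C(=O)O"),
    ("Selegiline", "C#CCN(C)[C@H](C)Cc1ccccc1"),
    ("Pramipexole", "CCCN[C@H]1CCc2nc(N)sc2C1"),
    ("Ropinirole", "CCCN(CCC)CCc1cccc2c1CC(=O)N2"),
    ("Baclofen", "NCC(CC(=O)O)c1ccc(Cl)cc1"),
    ("Tizanidine", "Clc1ccc2nsnc2c1NC1=NCCN1"),
    ("Sibutramine-des", "CC(C)CC(N(C)C)C1(c2ccc(Cl)cc2)CCC1"),
    ("Orlistat", "CCCCCCCCCCC[C@H](C[C@@H]1OC(=O)[C@H]1CCCCCC)OC(=O)[C@H](CC(C)C)NC=O"),
    ("Ezetimibe", "O[C@@H](CC[C@H]1[C@@H](c2ccc(O)cc2)N(c2ccc(F)cc2)C1=O)c1ccc(F)cc1"),
    ("Niacin", "OC(=O)c1cccnc1"),
    ("Ascorbate", "OC[C@H](O)[C@H]1OC(=O)C(O)=C1O"),
    ("Riboflavin", "Cc1cc2nc3c(=O)[nH]c(=O)nc-3n(C[C@H](O)[C@H](O)[C@H](O)CO)c2cc1C"),
    ("Thiamine-ol", "Cc1ncc(CN2C=C(C)C(CCO)=C2)c(N)n1"),
    ("Pyridoxine", "Cc1ncc(CO)c(CO)c1O"),
    ("Folate", "Nc1nc2ncc(CNc3ccc(C(=O)N[C@@H](CCC(=O)O)C(=O)O)cc3)nc2c(=O)[nH]1"),
    ("Sildenafil-d", "CCCc1nn(C)c2c(=O)[nH]c(-c3cc(S(=O)(=O)N4CCNCC4)ccc3OCC)nc12"),
    ("Tadalafil", "CN1CC(=O)N2[C@@H](Cc3c([nH]c4ccccc34)[C@@H]2c2ccc3OCOc3c2)C1=O"),
    ("Tolterodine", "CC(C)N(CC[C@H](c1ccccc1)c1cc(C)ccc1O)C(C)C"),
    ("Oxybutynin", "CCN(CC)CC#CCOC(=O)C(O)(C1CCCCC1)c1ccccc1"),
    ("Mirabegron", "NC(=O)c1csc(NCc2ccc(CCNC[C@H](O)c3ccccc3)cc2)n1"),
    ("Dutasteride", "C[C@]12CC[C@H]3[C@@H](CC[C@H]4NC(=O)C=C[C@]34C)[C@@H]1CC[C@@H]2C(=O)Nc1ccc(C(F)(F)F)cc1C(F)(F)F"),
    ("Bicalutamide", "CC(O)(CS(=O)(=O)c1ccc(F)cc1)C(=O)Nc1ccc(C#N)c(C(F)(F)F)c1"),
    ("Anastrozole", "CC(C)(C#N)c1cc(Cn2cncn2)cc(C(C)(C)C#N)c1"),
    ("Letrozole", "N#Cc1ccc(C(c2ccc(C#N)cc2)n2cncn2)cc1"),
    ("Bosentan", "CC(C)(C)c1ccc(S(=O)(=O)Nc2nc(-c3ccccn3)nc(OCCO)c2Oc2ccccc2OC)cc1"),
    ("Ambrisentan", "COC(c1ccccc1)(c1ccccc1)[C@@H](Cc1nc(C)cc(C)n1)C(=O)O"),
    ("Riociguat", "COC(=O)N(C)c1c(N)nc(-c2nn(Cc3ccccc3F)c3ncccc23)nc1N"),
    ("Apixaban", "COc1ccc(-n2nc(C(N)=O)c3CCN(c4ccc(N5CCCCC5=O)cc4)C(=O)c32)cc1"),
    ("Rivaroxaban", "O=C(NC[C@H]1CN(c2ccc(N3CCOCC3=O)cc2)C(=O)O1)c1ccc(Cl)s1"),
    ("Dabigatran-core", "Cn1c(CNc2ccc(C(=N)N)cc2)nc2cc(C(=O)N(CCC(=O)O)c3ccccn3)ccc21"),
    ("Propafenone", "CCCNCC(O)COc1ccccc1C(=O)CCc1ccccc1"),
    ("Cilostazol", "O=C1CCc2cc(OCCCCc3nnnn3C3CCCCC3)ccc2N1"),
    ("Pentoxifylline", "Cn1c(=O)c2c(ncn2C)n(CCCCC(C)=O)c1=O"),
    ("Dipyridamole", "OCCN(CCO)c1nc2c(N3CCCCC3)nc(N(CCO)CCO)nc2c(N3CCCCC3)n1"),
    ("Nicorandil", "O=[N+]([O-])OCCNC(=O)c1cccnc1"),
    ("Trimetazidine", "COc1cc2c(cc1OC)C(N1CCNCC1)CC2"
     ),
]
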