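5-fluorouracil
alpelisib
capecitabine
carboplatin
cisplatin
cyclophosphamide
docetaxel
doxorubicin
epirubicin
fulvestrant
gemcitabine
ixabepilone
lapatinib
methotrexate
neratinib
olaparib
paclitaxel
tucatinib
vinorelbine
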