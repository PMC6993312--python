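alias,canonical_name,oral_only,rarely_prophylactic,text_search_excluded
cefazolin,cefazolin,false,false,false
ancef,cefazolin,false,false,false
kefzol,cefazolin,false,false,false
cefazolen,cefazolin,false,false,false
cephazolin,cefazolin,false,false,false
cefuroxime,cefuroxime,false,false,false
zinacef,cefuroxime,false,false,false
ceftin,cefuroxime,false,false,false
cefuroxamine,cefuroxime,false,false,false
ceftriaxone,ceftriaxone,false,false,false
rocephin,ceftriaxone,false,false,false
ceftriaxon,ceftriaxone,false,false,false
vancomycin,vancomycin,false,false,false
vancocin,vancomycin,false,false,false
vancomicin,vancomycin,false,false,false
vanco,vancomycin,false,false,false
clindamycin,clindamycin,false,false,false
cleocin,clindamycin,false,false,false
clindamicin,clindamycin,false,false,false
gentamicin,gentamicin,false,false,false
garamycin,gentamicin,false,false,false
gentamycin,gentamicin,false,false,false
cephalexin,cephalexin,true,false,false
keflex,cephalexin,true,false,false
cephalexen,cephalexin,true,false,false
amoxicillin,amoxicillin,true,true,false
amoxil,amoxicillin,true,true,false
levofloxacin,levofloxacin,false,true,false
levaquin,levofloxacin,false,true,false
ciprofloxacin,ciprofloxacin,false,true,false
cipro,ciprofloxacin,false,true,false
azithromycin,azithromycin,false,true,false
zithromax,azithromycin,false,true,false
bacitracin,bacitracin,false,true,false
penicillin,penicillin,false,true,true
pcn,penicillin,false,true,true
penicillen,penicillin,false,true,true
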