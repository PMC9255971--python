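drug_a,drug_b,severity
warfarin,aspirin,D
warfarin,ibuprofen,D
warfarin,naproxen,D
warfarin,celecoxib,D
warfarin,amiodarone,D
warfarin,prednisone,C
warfarin,fish oil,C
warfarin,ginkgo biloba,D
warfarin,coenzyme q10,C
warfarin,glucosamine,C
warfarin,fluorouracil,D
warfarin,capecitabine,X
simvastatin,amiodarone,D
simvastatin,gemfibrozil,X
simvastatin,diltiazem,D
simvastatin,verapamil,D
atorvastatin,gemfibrozil,D
lisinopril,spironolactone,D
lisinopril,potassium chloride,C
lisinopril,ibuprofen,C
losartan,spironolactone,D
meloxicam,lisinopril,C
furosemide,digoxin,C
hydrochlorothiazide,digoxin,C
digoxin,amiodarone,D
digoxin,verapamil,D
metoprolol,verapamil,D
metoprolol,diltiazem,D
albuterol,metoprolol,C
glipizide,metoprolol,C
insulin glargine,metoprolol,C
clopidogrel,omeprazole,D
clopidogrel,esomeprazole,D
apixaban,aspirin,D
rivaroxaban,aspirin,D
enoxaparin,aspirin,C
potassium chloride,spironolactone,X
metformin,prednisone,C
prednisone,ibuprofen,D
aspirin,ibuprofen,C
aspirin,prednisone,C
sertraline,tramadol,D
fluoxetine,tramadol,D
venlafaxine,tramadol,D
amitriptyline,tramadol,D
trazodone,tramadol,C
sertraline,st johns wort,X
fluoxetine,st johns wort,X
citalopram,omeprazole,C
amitriptyline,diphenhydramine,C
lorazepam,oxycodone,D
alprazolam,oxycodone,D
diazepam,omeprazole,C
zolpidem,lorazepam,C
morphine,gabapentin,C
oxycodone,gabapentin,C
quetiapine,diphenhydramine,C
donepezil,metoprolol,C
donepezil,oxybutynin,C
levothyroxine,calcium carbonate,D
levothyroxine,ferrous sulfate,D
levothyroxine,omeprazole,C
calcium carbonate,ferrous sulfate,C
calcium carbonate,amlodipine,C
ondansetron,amiodarone,D
omeprazole,erlotinib,X
pantoprazole,erlotinib,D
omeprazole,capecitabine,D
aspirin,pemetrexed,C
ibuprofen,pemetrexed,D
naproxen,pemetrexed,D
st johns wort,irinotecan,X
st johns wort,erlotinib,D
fluoxetine,tamoxifen,D
sertraline,tamoxifen,C
furosemide,cisplatin,D
hydrochlorothiazide,carboplatin,C
metformin,cisplatin,C
amiodarone,paclitaxel,C
verapamil,docetaxel,D
diltiazem,docetaxel,C
spironolactone,abiraterone,D
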