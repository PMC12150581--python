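indicator_id,clinical_area,label,group,indicator_type,reverse_coded,population_size,adverse_events
2163,Breast surgery,Primary axillary dissection in DCIS,program,indication,False,54287,101
52279,Breast surgery,Intraoperative specimen sonography or x-ray with sonographic wire marking,program,process,True,188749,18246
52330,Breast surgery,Intraoperative specimen sonography or x-ray with mammographic wire marking,program,process,True,157010,2273
10211,Gynecological surgery,Complete removal of the ovary or adnexa without pathological findings,program,indication,False,130503,13694
12874,Gynecological surgery,Missing histology after isolated ovarian surgery with tissue removal,program,indication,False,301726,3927
1058,Obstetrics,D-D time in emergency cesarean section > 20 min,program,process,False,76475,340
318,Obstetrics,Presence of a paediatrician at premature births,program,process,True,203198,7253
330,Obstetrics,Antenatal corticosteroid therapy in premature births with prepartum hospitalization for at least two calendar days,program,process,True,61027,2048
50045,Obstetrics,Perioperative antibiotic prophylaxis in cesarean section delivery,program,process,True,1827564,25805
51437,Carotid artery revascularization,Indication in asymptomatic carotid artery stenosis - catheter-supported,control,indication,True,24242,630
51443,Carotid artery revascularization,Indication in symptomatic carotid artery stenosis - catheter-supported,control,indication,True,15261,152
603,Carotid artery revascularization,Indication in asymptomatic carotid artery stenosis - open surgery,control,indication,True,113245,1669
604,Carotid artery revascularization,Indication in symptomatic carotid artery stenosis - open surgery,control,indication,True,72008,393
2005,Community-acquired pneumonia,First blood gas analysis or pulse oximetry within 8 h after admission,control,process,True,2182966,38560
2009,Community-acquired pneumonia,Antimicrobial therapy within 8 h after hospitalization,control,process,True,1774816,87175
2013,Community-acquired pneumonia,Early mobilization within 24 h after admission for risk class 1,control,process,True,1047287,71615
2028,Community-acquired pneumonia,Completely measured clinical stability criteria at discharge,control,process,True,1387236,65062
50722,Community-acquired pneumonia,Determination of respiratory rate on admission,control,process,True,2136942,88926
50063,Neonatology,Hearing test performed,control,process,True,759748,20548
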