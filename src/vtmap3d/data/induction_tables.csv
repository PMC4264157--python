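dog_id,group,cohort,induction_index,episode_type,mechanisms,sustained_flag
A1,APO,APO,1,VT,EpFo,1
A1,APO,APO,2,VT,EpFo,1
A1,APO,APO,3,NI,,0
A1,APO,APO,4,NI,,0
A2,APO,APO,1,VF,EFo;RE,1
A2,APO,APO,2,VF,EFo;RE,1
A2,APO,APO,3,VF,EFo;R,1
A2,APO,APO,4,nd,,0
A3,APO,APO,1,VF,EFo;RE,1
A3,APO,APO,2,VT,EFo,1
A3,APO,APO,3,NI,,0
A3,APO,APO,4,nd,,0
A4,APO,APO,1,VT,EFo;R,1
A4,APO,APO,2,VT,EFo;R,1
A4,APO,APO,3,VT_ns,EFo,0
A4,APO,APO,4,NI,,0
A5,APO,APO,1,VT,EFo,1
A5,APO,APO,2,VT,EFo,1
A5,APO,APO,3,VT,EFo,1
A5,APO,APO,4,VF,EFo;RE,1
A6,APO,APO,1,VF,EFo;RE,1
A6,APO,APO,2,VF,EFo;R,1
A6,APO,APO,3,VF,EFo,1
A6,APO,APO,4,VT,EFo;R,1
A7,APO,APO,1,VF,EpFo;R,1
A7,APO,APO,2,VF,EpFo;R,1
A7,APO,APO,3,VF,EFo;R,1
A7,APO,APO,4,VT,EpFo;R,1
A8,APO,APO,1,VT,EFo,1
A8,APO,APO,2,VF,EFo;R,1
A8,APO,APO,3,VT_ns,EFo,0
A8,APO,APO,4,VT_ns,EFo,0
A9,APO,APO,1,VT,EFo;R,1
A9,APO,APO,2,VF,EFo;R,1
A9,APO,APO,3,NI,,0
A9,APO,APO,4,VT_ns,EFo,0
A10,APO,APO,1,VF,EFo,1
A10,APO,APO,2,VF,EFo;RE,1
A10,APO,APO,3,VT,EFo,1
A10,APO,APO,4,NI,,0
C1,CONTROL,APO,1,VT,EpFo,1
C1,CONTROL,APO,2,VT,EpFo,1
C1,CONTROL,APO,3,VT,EFo,1
C1,CONTROL,APO,4,VT,EpFo,1
C2,CONTROL,APO,1,VF,R,1
C2,CONTROL,APO,2,VT,R,1
C2,CONTROL,APO,3,VT,R,1
C2,CONTROL,APO,4,nd,,0
C3,CONTROL,APO,1,VT,R,1
C3,CONTROL,APO,2,VT,R,1
C3,CONTROL,APO,3,VT,R,1
C3,CONTROL,APO,4,VT,R,1
C4,CONTROL,APO,1,VT,R,1
C4,CONTROL,APO,2,VT,R,1
C4,CONTROL,APO,3,VT,R,1
C4,CONTROL,APO,4,VT,R,1
C5,CONTROL,APO,1,VT,R,1
C5,CONTROL,APO,2,VT,R,1
C5,CONTROL,APO,3,VT,R,1
C5,CONTROL,APO,4,VT,R,1
C6,CONTROL,APO,1,VF,EFo;R,1
C6,CONTROL,APO,2,VT,EFo,1
C6,CONTROL,APO,3,VF,EpFo,1
C6,CONTROL,APO,4,VT,EFo,1
C7,CONTROL,APO,1,VF,EFo;R,1
C7,CONTROL,APO,2,VF,EFo;R,1
C7,CONTROL,APO,3,VF,EFo;R,1
C7,CONTROL,APO,4,VF,EFo;R,1
C8,CONTROL,APO,1,VF,EFo;R,1
C8,CONTROL,APO,2,VF,EFo;RE,1
C8,CONTROL,APO,3,VT,EpFo;RE,1
C8,CONTROL,APO,4,VT,EFo;R,1
C9,CONTROL,APO,1,VT,R,1
C9,CONTROL,APO,2,VT,RE,1
C9,CONTROL,APO,3,VF,EFo;RE,1
C9,CONTROL,APO,4,VT,R,1
C10,CONTROL,APO,1,VF,EFo,1
C10,CONTROL,APO,2,VF,EFo;RE,1
C10,CONTROL,APO,3,VF,EFo;RE,1
C10,CONTROL,APO,4,VF,EFo;R,1
O1,OXY,OXY,1,VF,EFo;RE,1
O1,OXY,OXY,2,VF,EFo;RE,1
O1,OXY,OXY,3,VT,EFo,1
O1,OXY,OXY,4,VT,EFo,1
O2,OXY,OXY,1,VT,R,1
O2,OXY,OXY,2,VF,RE,1
O2,OXY,OXY,3,VT,RE,1
O2,OXY,OXY,4,nd,,0
O3,OXY,OXY,1,VT,R,1
O3,OXY,OXY,2,VT,R,1
O3,OXY,OXY,3,VT,R,1
O3,OXY,OXY,4,VT,R,1
O4,OXY,OXY,1,VT,EFo;RE,1
O4,OXY,OXY,2,VT,EFo;RE,1
O4,OXY,OXY,3,NI,,0
O4,OXY,OXY,4,NI,,0
O5,OXY,OXY,1,VF,RE,1
O5,OXY,OXY,2,VF,R,1
O5,OXY,OXY,3,VT,R,1
O5,OXY,OXY,4,VF,R,1
O6,OXY,OXY,1,VF,EFo,1
O6,OXY,OXY,2,VT,EFo,1
O6,OXY,OXY,3,VF,EFo,1
O6,OXY,OXY,4,VF,EFo,1
O7,OXY,OXY,1,VF,R,1
O7,OXY,OXY,2,VF,R,1
O7,OXY,OXY,3,VT,RE,1
O7,OXY,OXY,4,VT,EFo;RE,1
O8,OXY,OXY,1,VT,EFo,1
O8,OXY,OXY,2,VF,EFo;RE,1
O8,OXY,OXY,3,VF,R,1
O8,OXY,OXY,4,VT_ns,R,0
O9,OXY,OXY,1,VF,R,1
O9,OXY,OXY,2,VF,RE,1
O9,OXY,OXY,3,VF,RE,1
O9,OXY,OXY,4,NI,,0
C11,CONTROL,OXY,1,VF,EFo;RE,1
C11,CONTROL,OXY,2,VF,R,1
C11,CONTROL,OXY,3,VF,EFo;RE,1
C11,CONTROL,OXY,4,VF,EFo;RE,1
C12,CONTROL,OXY,1,VT,R,1
C12,CONTROL,OXY,2,VF,EpFo;R,1
C12,CONTROL,OXY,3,VF,R,1
C12,CONTROL,OXY,4,VF,R,1
C13,CONTROL,OXY,1,VF,EpFo;R,1
C13,CONTROL,OXY,2,VF,RE,1
C13,CONTROL,OXY,3,VF,RE,1
C13,CONTROL,OXY,4,VF,RE,1
C14,CONTROL,OXY,1,VT,RE,1
C14,CONTROL,OXY,2,VT,RE,1
C14,CONTROL,OXY,3,VT,RE,1
C14,CONTROL,OXY,4,VT,RE,1
C15,CONTROL,OXY,1,VF,EFo;R,1
C15,CONTROL,OXY,2,VF,R,1
C15,CONTROL,OXY,3,VF,R,1
C15,CONTROL,OXY,4,VF,EFo;R,1
C16,CONTROL,OXY,1,VF,R,1
C16,CONTROL,OXY,2,VF,EFo;R,1
C16,CONTROL,OXY,3,VF,EFo;RE,1
C16,CONTROL,OXY,4,VF,R,1
C17,CONTROL,OXY,1,VF,RE,1
C17,CONTROL,OXY,2,VT,R,1
C17,CONTROL,OXY,3,VF,R,1
C17,CONTROL,OXY,4,VT,R,1
C18,CONTROL,OXY,1,VT,EFo,1
C18,CONTROL,OXY,2,VF,EFo;R,1
C18,CONTROL,OXY,3,VT,EFo,1
C18,CONTROL,OXY,4,VT,EFo,1
C19,CONTROL,OXY,1,VF,EFo;RE,1
C19,CONTROL,OXY,2,VT,R,1
C19,CONTROL,OXY,3,VT,R,1
C19,CONTROL,OXY,4,VT,R,1
B1,BOTH,BOTH,1,VT,EpFo;R,1
B1,BOTH,BOTH,2,VT,EpFo;R,1
B1,BOTH,BOTH,3,VT,R,1
B1,BOTH,BOTH,4,VT,R,1
B2,BOTH,BOTH,1,VT,EFo,1
B2,BOTH,BOTH,2,VT,EFo,1
B2,BOTH,BOTH,3,VT_ns,EFo,0
B2,BOTH,BOTH,4,NI,,0
B3,BOTH,BOTH,1,VT,R,1
B3,BOTH,BOTH,2,VT,R,1
B3,BOTH,BOTH,3,VT,R,1
B3,BOTH,BOTH,4,nd,,0
B4,BOTH,BOTH,1,VT,R,1
B4,BOTH,BOTH,2,VT,R,1
B4,BOTH,BOTH,3,VT,R,1
B4,BOTH,BOTH,4,VT,R,1
B5,BOTH,BOTH,1,VT,EFo,1
B5,BOTH,BOTH,2,VT,EFo,1
B5,BOTH,BOTH,3,VT,EFo,1
B5,BOTH,BOTH,4,nd,,0
B6,BOTH,BOTH,1,VT,RE,1
B6,BOTH,BOTH,2,VT,RE,1
B6,BOTH,BOTH,3,NI,,0
B6,BOTH,BOTH,4,NI,,0
B7,BOTH,BOTH,1,VT,EFo,1
B7,BOTH,BOTH,2,VT,EFo,1
B7,BOTH,BOTH,3,NI,,0
B7,BOTH,BOTH,4,NI,,0
B8,BOTH,BOTH,1,VF,EFo;RE,1
B8,BOTH,BOTH,2,VF,RE,1
B8,BOTH,BOTH,3,VF,EFo;RE,1
B8,BOTH,BOTH,4,NI,,0
C20,CONTROL,BOTH,1,VF,EFo;RE,1
C20,CONTROL,BOTH,2,VT,EFo;R,1
C20,CONTROL,BOTH,3,VT,EFo;R,1
C20,CONTROL,BOTH,4,VT,EFo;R,1
C21,CONTROL,BOTH,1,VT,R,1
C21,CONTROL,BOTH,2,VT,R,1
C21,CONTROL,BOTH,3,VT,R,1
C21,CONTROL,BOTH,4,VT,R,1
C22,CONTROL,BOTH,1,VF,RE,1
C22,CONTROL,BOTH,2,VT,R,1
C22,CONTROL,BOTH,3,VT,R,1
C22,CONTROL,BOTH,4,VT,R,1
C23,CONTROL,BOTH,1,VT,R,1
C23,CONTROL,BOTH,2,VF,EFo;R,1
C23,CONTROL,BOTH,3,VF,EFo;R,1
C23,CONTROL,BOTH,4,VT,EFo,1
C24,CONTROL,BOTH,1,VT,EFo;R,1
C24,CONTROL,BOTH,2,VT,EFo;RE,1
C24,CONTROL,BOTH,3,VF,EFo;R,1
C24,CONTROL,BOTH,4,VT,EFo;R,1
C25,CONTROL,BOTH,1,VT,EpFo,1
C25,CONTROL,BOTH,2,VT,EpFo,1
C25,CONTROL,BOTH,3,VT,EpFo,1
C25,CONTROL,BOTH,4,VT,EpFo,1
C26,CONTROL,BOTH,1,VT,EFo;R,1
C26,CONTROL,BOTH,2,VT,EFo,1
C26,CONTROL,BOTH,3,VT,EFo,1
C26,CONTROL,BOTH,4,VT,EFo,1
C27,CONTROL,BOTH,1,VF,EFo,1
C27,CONTROL,BOTH,2,VT,EFo,1
C27,CONTROL,BOTH,3,VT,EFo;R,1
C27,CONTROL,BOTH,4,VT,EpFo,1
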